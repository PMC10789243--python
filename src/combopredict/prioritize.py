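"""Merge CGEM and TargOpt rankings and attach triage annotations.

The two engines see different evidence (transcriptional reversal versus
target coverage); a pair surfaced by both is the strongest kind of
candidate.  Aggregation is mean rank: a pair present in only one list
receives, for the missing method, the worst rank in that method's list
plus one, and is flagged ``single_method_only``.  Annotation flags
(drug–drug-interaction alerts, shared mechanism class) inform the human
expert who makes the final call — they never filter or reorder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .sigio import SigIOError

__all__ = ["CombinationPrediction", "aggregate_ranks", "annotate",
           "predictions_frame"]

FLAGS = frozenset({"ddi_alert", "same_mechanism", "single_method_only"})

Pair = tuple[str, str]


def _norm_pair(pair: Sequence[str]) -> Pair:
    a, b = pair
    if a == b:
        raise SigIOError(f"pair members must be distinct, got {a!r} twice")
    return (a, b) if a <= b else (b, a)


@dataclass
class CombinationPrediction:
    """A candidate pair with per-method ranks, aggregate rank and flags."""

    pair: Pair
    cgem_rank: int | None
    targopt_rank: int | None
    aggregate_rank: float
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.pair = _norm_pair(self.pair)
        unknown = self.flags - FLAGS
        if unknown:
            raise SigIOError(f"unknown flags: {sorted(unknown)}")


def aggregate_ranks(cgem: Sequence[Sequence[str]], targopt: Sequence[Sequence[str]],
                    method: str = "mean_rank") -> list[CombinationPrediction]:
    """Merge two ranked pair lists into aggregate-ranked predictions.

    Inputs are pair sequences in rank order (position 1 = rank 1).  Output
    covers exactly the union of input pairs, sorted ascending by aggregate
    rank, ties by pair id.
    """
    if method != "mean_rank":
        raise SigIOError(f"unknown aggregation method: {method!r}")
    if not cgem and not targopt:
        raise SigIOError("both ranked lists are empty: nothing to aggregate")

    cgem_ranks = {_norm_pair(p): i + 1 for i, p in enumerate(cgem)}
    targopt_ranks = {_norm_pair(p): i + 1 for i, p in enumerate(targopt)}
    cgem_penalty = len(cgem_ranks) + 1
    targopt_penalty = len(targopt_ranks) + 1

    predictions = []
    for pair in sorted(set(cgem_ranks) | set(targopt_ranks)):
        rc = cgem_ranks.get(pair)
        rt = targopt_ranks.get(pair)
        flags: set[str] = set()
        if rc is None or rt is None:
            flags.add("single_method_only")
        aggregate = ((rc if rc is not None else cgem_penalty)
                     + (rt if rt is not None else targopt_penalty)) / 2.0
        predictions.append(CombinationPrediction(pair, rc, rt, aggregate, flags))
    predictions.sort(key=lambda p: (p.aggregate_rank, p.pair))
    return predictions


def annotate(predictions: Iterable[CombinationPrediction],
             ddi_blocklist: Iterable[Sequence[str]] = (),
             mechanism_map: Mapping[str, str] | None = None,
             ) -> list[CombinationPrediction]:
    """Attach ddi_alert / same_mechanism flags in place; never drops a pair.

    A pair on the drug–drug-interaction blocklist gets ``ddi_alert``; a
    pair whose drugs share a mechanism class gets ``same_mechanism``.
    Drugs missing from the mechanism map simply get no flag.
    """
    blocked = {_norm_pair(p) for p in ddi_blocklist}
    mech = mechanism_map or {}
    predictions = list(predictions)
    for pred in predictions:
        if pred.pair in blocked:
            pred.flags.add("ddi_alert")
        a, b = pred.pair
        if a in mech and b in mech and mech[a] == mech[b]:
            pred.flags.add("same_mechanism")
    return predictions


def predictions_frame(predictions: Sequence[CombinationPrediction]) -> pd.DataFrame:
    """Tidy prediction table; flags serialized as semicolon-joined tokens."""
    return pd.DataFrame(
        {
            "drug_a": [p.pair[0] for p in predictions],
            "drug_b": [p.pair[1] for p in predictions],
            "cgem_rank": [p.cgem_rank if p.cgem_rank is not None else ""
                          for p in predictions],
            "targopt_rank": [p.targopt_rank if p.targopt_rank is not None else ""
                             for p in predictions],
            "aggregate_rank": [p.aggregate_rank for p in predictions],
            "flags": [";".join(sorted(p.flags)) for p in predictions],
        }
    )
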