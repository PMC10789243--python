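"""TargOpt — rank drug pairs by on-target coverage versus off-target burden.

Given a catalogue of drug→(target, direction) interactions and a wish-list
of disease targets with desired modulation directions, a pair is scored

    score = α·on_count − β·off_count

where ``on_count`` counts disease targets engaged in the desired direction
by at least one drug of the pair (each counted once), and ``off_count``
counts distinct targets engaged by either drug that are not disease
targets or are pushed in the wrong direction.  Wrong-direction engagement
of a disease target is treated as a liability (off-target), not merely a
missed on-target.

The trade-off weights default to α=1, β=0.5; because the scalarization is
a modelling choice, rankings also annotate the (on_count, off_count)
Pareto front so a non-dominated pair is visible regardless of weights.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .sigio import SigIOError

logger = logging.getLogger(__name__)

__all__ = ["TargetCatalog", "TargOptScore", "targopt_score",
           "targopt_rank_pairs", "pareto_front", "read_target_catalog",
           "read_disease_targets", "targopt_scores_frame"]

ACTIVATION = +1
INHIBITION = -1

Engagement = tuple[str, int]  # (target_id, direction)


def _check_direction(value: int, context: str) -> int:
    if value not in (ACTIVATION, INHIBITION):
        raise SigIOError(f"{context}: direction must be +1 or -1, got {value!r}")
    return int(value)


@dataclass
class TargetCatalog:
    """Drug→target engagements plus the disease's desired target directions.

    ``drug_targets`` maps drug id to a set of (target_id, direction) with
    direction +1 (activation/agonism) or −1 (inhibition/antagonism);
    ``disease_targets`` maps target id to its desired direction.
    """

    drug_targets: dict[str, frozenset[Engagement]]
    disease_targets: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, frozenset[Engagement]] = {}
        for drug, engagements in self.drug_targets.items():
            clean[drug] = frozenset(
                (t, _check_direction(d, f"drug {drug!r}, target {t!r}"))
                for t, d in engagements
            )
        self.drug_targets = clean
        self.disease_targets = {
            t: _check_direction(d, f"disease target {t!r}")
            for t, d in self.disease_targets.items()
        }

    @property
    def drugs(self) -> list[str]:
        return list(self.drug_targets)


@dataclass(frozen=True)
class TargOptScore:
    """A drug pair's on/off-target counts and weighted score."""

    pair: tuple[str, str]
    on_count: int
    off_count: int
    score: float

    def __post_init__(self) -> None:
        a, b = self.pair
        if a == b:
            raise SigIOError(f"pair members must be distinct, got {a!r} twice")
        object.__setattr__(self, "pair", (a, b) if a <= b else (b, a))


def targopt_score(targets_a: frozenset[Engagement], targets_b: frozenset[Engagement],
                  disease: dict[str, int], alpha: float = 1.0, beta: float = 0.5,
                  pair: tuple[str, str] = ("a", "b")) -> TargOptScore:
    """Score one pair's joint target profile against the disease wish-list."""
    if alpha < 0 or beta < 0:
        raise SigIOError("alpha and beta must be non-negative")
    union = set()
    for t, d in itertools.chain(targets_a, targets_b):
        union.add((t, _check_direction(d, f"target {t!r}")))
    on = {t for t, d in union if disease.get(t) == d}
    off = {t for t, d in union if disease.get(t) != d}
    score = alpha * len(on) - beta * len(off)
    return TargOptScore(pair, len(on), len(off), score)


def targopt_rank_pairs(catalog: TargetCatalog, drugs: list[str] | None = None,
                       alpha: float = 1.0, beta: float = 0.5,
                       top_k: int | None = None) -> list[TargOptScore]:
    """Exhaustively score all unordered drug pairs and rank them.

    Sorted by score descending, ties by higher on_count then lexicographic
    pair id.  A drug absent from the catalogue is an error naming it.
    """
    if drugs is None:
        drugs = sorted(catalog.drug_targets)
    else:
        for d in drugs:
            if d not in catalog.drug_targets:
                raise SigIOError(f"drug not in target catalogue: {d!r}")
        drugs = sorted(drugs)
    if len(drugs) < 2:
        raise SigIOError("need at least 2 drugs to form pairs")

    logger.info("TargOpt: scoring %d pairs from %d drugs",
                len(drugs) * (len(drugs) - 1) // 2, len(drugs))
    scored = [
        targopt_score(catalog.drug_targets[a], catalog.drug_targets[b],
                      catalog.disease_targets, alpha, beta, pair=(a, b))
        for a, b in itertools.combinations(drugs, 2)
    ]
    scored.sort(key=lambda s: (-s.score, -s.on_count, s.pair))
    if top_k is not None:
        if top_k < 1:
            raise SigIOError("top_k must be >= 1")
        scored = scored[:top_k]
    return scored


def pareto_front(scores: list[TargOptScore]) -> set[tuple[str, str]]:
    """Pairs not dominated in (maximize on_count, minimize off_count)."""
    front: set[tuple[str, str]] = set()
    for s in scores:
        dominated = any(
            (o.on_count >= s.on_count and o.off_count <= s.off_count)
            and (o.on_count > s.on_count or o.off_count < s.off_count)
            for o in scores
        )
        if not dominated:
            front.add(s.pair)
    return front


def targopt_scores_frame(scores: list[TargOptScore]) -> pd.DataFrame:
    """Tidy ranking table with a Pareto-front annotation column."""
    front = pareto_front(scores)
    return pd.DataFrame(
        {
            "rank": range(1, len(scores) + 1),
            "drug_a": [s.pair[0] for s in scores],
            "drug_b": [s.pair[1] for s in scores],
            "on_count": [s.on_count for s in scores],
            "off_count": [s.off_count for s in scores],
            "score": [s.score for s in scores],
            "pareto": [s.pair in front for s in scores],
        }
    )


def read_target_catalog(path: str | Path,
                        disease_path: str | Path | None = None) -> TargetCatalog:
    """Read drug→target TSV (drug_id, target_id, direction) and optionally
    a disease-target TSV (target_id, desired_direction)."""
    frame = pd.read_csv(path, sep="\t", dtype={"drug_id": str, "target_id": str})
    required = {"drug_id", "target_id", "direction"}
    if not required.issubset(frame.columns):
        raise SigIOError(f"{path}: need columns {sorted(required)}")
    drug_targets: dict[str, set[Engagement]] = {}
    for row in frame.itertuples(index=False):
        drug_targets.setdefault(row.drug_id, set()).add(
            (row.target_id, int(row.direction)))
    disease = read_disease_targets(disease_path) if disease_path else {}
    return TargetCatalog({d: frozenset(v) for d, v in drug_targets.items()}, disease)


def read_disease_targets(path: str | Path) -> dict[str, int]:
    frame = pd.read_csv(path, sep="\t", dtype={"target_id": str})
    required = {"target_id", "desired_direction"}
    if not required.issubset(frame.columns):
        raise SigIOError(f"{path}: need columns {sorted(required)}")
    if frame["target_id"].duplicated().any():
        dup = frame.loc[frame["target_id"].duplicated(), "target_id"].iloc[0]
        raise SigIOError(f"{path}: duplicate disease target {dup!r}")
    return {r.target_id: int(r.desired_direction) for r in frame.itertuples(index=False)}
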