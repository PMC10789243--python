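"""Kolmogorov–Smirnov enrichment and connectivity (reversal) scoring.

Connectivity mapping asks where a disease's up- and down-regulated gene
sets fall in a compound's ranked expression profile.  A compound that
pushes the disease's up-genes to the bottom of its ranking and the
down-genes to the top *reverses* the disease signature — the property the
combination search maximizes.

The enrichment statistic is the classic unweighted KS running-sum: the
maximal deviation between the empirical distribution of a gene set's rank
positions and the uniform distribution, signed by whether the set
concentrates at the top (+) or bottom (−) of the list.  The two-set
combination is sign-gated: when up- and down-set enrichments share a sign
the profile neither mimics nor reverses the disease coherently and the
connectivity is 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .sigio import DiseaseSignature, RankedSignature, SigIOError

__all__ = ["EnrichmentResult", "ks_enrichment", "connectivity_score"]


@dataclass(frozen=True)
class EnrichmentResult:
    """Up/down-set enrichments and their sign-gated combination.

    ``connectivity`` > 0 means the profile mimics the disease signature,
    < 0 means it reverses it; ``reversal`` is its negation so that larger
    is better for therapy.  All four values lie in [−1, 1].
    """

    es_up: float
    es_down: float
    connectivity: float

    @property
    def reversal(self) -> float:
        return -self.connectivity


def ks_enrichment_positions(positions: np.ndarray, n: int) -> float:
    """KS enrichment from sorted 1-based rank positions of set members.

    With p(1)<…<p(t) the member positions in a list of length n, computes
    a = max_j (j/t − p(j)/n) (top concentration) and
    b = max_j (p(j)/n − (j−1)/t) (bottom concentration) and returns
    ``a`` if a > b else ``−b``.  Result in [−1, 1].
    """
    p = np.asarray(positions, dtype=float)
    t = p.size
    if t == 0:
        raise SigIOError("empty gene set: nothing to enrich")
    j = np.arange(1, t + 1, dtype=float)
    a = float(np.max(j / t - p / n))
    b = float(np.max(p / n - (j - 1) / t))
    return a if a > b else -b


def ks_enrichment(ranks: np.ndarray, member_positions: Iterable[int] | np.ndarray,
                  *, by_index: bool = True) -> float:
    """KS enrichment of a gene set within a ranked list.

    ``ranks`` is the per-gene rank vector (permutation of 1..n, 1 = top);
    ``member_positions`` are the universe indices of set members when
    ``by_index`` (default), otherwise already-1-based rank positions.
    """
    ranks = np.asarray(ranks)
    n = ranks.size
    idx = np.asarray(list(member_positions) if not isinstance(
        member_positions, np.ndarray) else member_positions, dtype=np.int64)
    if idx.size == 0:
        raise SigIOError("empty gene set: nothing to enrich")
    if by_index:
        if idx.min() < 0 or idx.max() >= n:
            raise SigIOError("gene-set member index outside the universe")
        pos = np.sort(ranks[idx])
    else:
        pos = np.sort(idx)
        if pos.min() < 1 or pos.max() > n:
            raise SigIOError("rank position outside 1..n")
    return ks_enrichment_positions(pos, n)


def combine_enrichments(es_up: float, es_down: float) -> float:
    """Sign-gated two-set connectivity: (es_up − es_down)/2, or 0 on same sign."""
    if np.sign(es_up) == np.sign(es_down):
        return 0.0
    return (es_up - es_down) / 2.0


def connectivity_score(sig: RankedSignature,
                       disease: DiseaseSignature) -> EnrichmentResult:
    """Score a disease signature against one ranked perturbation profile.

    The disease signature must already be harmonized to the signature's
    universe (members absent from it raise).
    """
    up_idx = sig.universe.positions(sorted(disease.up))
    down_idx = sig.universe.positions(sorted(disease.down))
    es_up = ks_enrichment(sig.rank, up_idx)
    es_down = ks_enrichment(sig.rank, down_idx)
    return EnrichmentResult(es_up, es_down, combine_enrichments(es_up, es_down))
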