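"""Synthetic pipeline inputs with planted ground truth.

Every stage of the combination-prediction pipeline can be exercised
without any external download: the generators here emit

* a compound library of i.i.d. standard-normal z-score signatures — a
  simplified stand-in for moderated z-scores from a large perturbation
  compendium (no batch or plate structure is emulated);
* a disease signature *reverse-engineered* from a chosen drug pair: the
  disease's up-genes are the genes the pair's combined signature pushes
  down hardest, and vice versa, so that pair is by construction the
  maximal reverser and recovery at zero noise is provable, not merely
  probable;
* a drug–target catalogue in which a planted pair jointly covers every
  disease target in the desired direction with zero off-targets while
  every other drug is strictly worse;
* behavioural cohorts with group-level effects, emulating the 10-animal
  per-group design of a typical phenotyping study.

All generators are pure functions of their arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .behaviour import BehaviourTrial
from .sigio import (CompoundLibrary, DiseaseSignature, GeneUniverse,
                    RankedSignature, SigIOError)
from .targopt import TargetCatalog

__all__ = ["PlantedTruth", "CohortGroup", "generate_library",
           "plant_reversal", "generate_target_catalog",
           "generate_behaviour_cohort", "default_behaviour_spec"]


@dataclass(frozen=True)
class PlantedTruth:
    """Record of a generator's embedded best answer."""

    planted_pair: tuple[str, str]
    noise_sigma: float
    seed: int
    disease: DiseaseSignature


def _gene_ids(n: int) -> tuple[str, ...]:
    width = max(4, len(str(n)))
    return tuple(f"g{i:0{width}d}" for i in range(1, n + 1))


def _compound_ids(m: int) -> list[str]:
    width = max(3, len(str(m)))
    return [f"cpd{i:0{width}d}" for i in range(1, m + 1)]


def generate_library(m: int, n: int, seed: int) -> CompoundLibrary:
    """m-compound, n-gene library of i.i.d. standard-normal z-scores.

    Gene ids are g0001..g<n>, compound ids cpd001..cpd<m>; fully
    deterministic given (m, n, seed).
    """
    if m < 2:
        raise SigIOError("need at least 2 compounds")
    if n < 10:
        raise SigIOError("need at least 10 genes")
    rng = np.random.default_rng(seed)
    universe = GeneUniverse(_gene_ids(n))
    z = rng.standard_normal((n, m))
    sigs = {
        cid: RankedSignature(cid, universe, z[:, i])
        for i, cid in enumerate(_compound_ids(m))
    }
    return CompoundLibrary(universe, sigs)


def plant_reversal(lib: CompoundLibrary, pair: tuple[str, str],
                   n_up: int = 50, n_down: int = 50, sigma: float = 0.0,
                   seed: int = 0) -> tuple[DiseaseSignature, PlantedTruth]:
    """Derive a disease signature that the given pair maximally reverses.

    The n_up genes with the most negative combined z (a.z + b.z) become
    the disease's up-set and the n_down most positive its down-set — the
    planted pair's combined ranking then places the up-set at the exact
    bottom and the down-set at the exact top, the largest reversal any
    pair of the given set sizes can achieve.  The whole library is then
    perturbed in place with N(0, sigma) measurement noise: at small sigma
    the planted pair's observed signature stays close to the one the
    disease sets were derived from and recovery is near-certain; when
    noise swamps the signal recovery degrades to chance.
    """
    a, b = pair
    for cid in pair:
        if cid not in lib.signatures:
            raise SigIOError(f"planted compound not in library: {cid!r}")
    n = len(lib.universe)
    if n_up < 1 or n_down < 1 or n_up + n_down > n:
        raise SigIOError(
            f"set sizes n_up={n_up}, n_down={n_down} invalid for {n} genes")

    combined = lib.signatures[a].z + lib.signatures[b].z
    order = np.argsort(combined)  # ascending
    genes = np.asarray(lib.universe.genes)
    up = frozenset(genes[order[:n_up]])           # most negative combined z
    down = frozenset(genes[order[-n_down:]])      # most positive combined z
    disease = DiseaseSignature("planted", up, down)

    if sigma > 0:
        rng = np.random.default_rng(seed)
        for cid in sorted(lib.signatures):
            noisy = lib.signatures[cid].z + rng.normal(0.0, sigma, size=n)
            lib.signatures[cid] = RankedSignature(cid, lib.universe, noisy)

    truth = PlantedTruth(tuple(sorted(pair)), float(sigma), int(seed), disease)
    return disease, truth


def generate_target_catalog(n_drugs: int, n_disease_targets: int,
                            n_decoy_targets: int, planted_pair: tuple[str, str],
                            seed: int = 0) -> TargetCatalog:
    """Target catalogue in which ``planted_pair`` is the unique optimum.

    The planted drugs split the disease targets between them, each engaged
    in the desired direction, with zero off-targets — pair score
    α·n_disease_targets.  Every other drug covers at most
    ⌈n_disease_targets/2⌉ disease targets and carries at least one decoy
    off-target, so for any β > 0 every competing pair scores strictly less.
    """
    if n_drugs < 2:
        raise SigIOError("need at least 2 drugs")
    if n_disease_targets < 1:
        raise SigIOError("need at least 1 disease target")
    if n_drugs > 2 and n_decoy_targets < 1:
        raise SigIOError("decoy drugs need at least 1 decoy target")
    a, b = planted_pair
    if a == b:
        raise SigIOError("planted pair members must be distinct")

    rng = np.random.default_rng(seed)
    dts = [f"DT{i:02d}" for i in range(1, n_disease_targets + 1)]
    decoys = [f"OT{i:02d}" for i in range(1, n_decoy_targets + 1)]
    disease = {t: int(d) for t, d in
               zip(dts, rng.choice([-1, 1], size=n_disease_targets))}

    half = n_disease_targets // 2
    drug_targets: dict[str, frozenset] = {
        a: frozenset((t, disease[t]) for t in dts[:half]) if half else frozenset(),
        b: frozenset((t, disease[t]) for t in dts[half:]),
    }
    if half == 0:
        # a single disease target: both planted drugs engage it
        drug_targets[a] = frozenset((t, disease[t]) for t in dts)

    max_cover = -(-n_disease_targets // 2)  # ceil
    others = [f"drug{i:03d}" for i in range(1, n_drugs - 1)]
    for name in others:
        k = int(rng.integers(0, max_cover + 1))
        covered = rng.choice(dts, size=k, replace=False) if k else []
        n_off = int(rng.integers(1, min(3, n_decoy_targets) + 1))
        offs = rng.choice(decoys, size=n_off, replace=False)
        drug_targets[name] = frozenset(
            [(t, disease[t]) for t in covered]
            + [(t, int(rng.choice([-1, 1]))) for t in offs])
    return TargetCatalog(drug_targets, disease)


@dataclass(frozen=True)
class CohortGroup:
    """Specification of one treatment group in a behavioural cohort.

    ``params`` maps trial fields (t_novel, t_familiar, latency, raw_value)
    to (mean, sd) of a normal distribution truncated at 0 seconds;
    ``p_no_event`` is the probability a hyponeophagia animal never drinks.
    """

    name: str
    n: int
    assay: str
    params: dict[str, tuple[float, float]] = field(default_factory=dict)
    p_no_event: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise SigIOError(f"group {self.name!r}: n must be >= 1")
        for fname, (mean, sd) in self.params.items():
            if sd < 0:
                raise SigIOError(f"group {self.name!r}: sd < 0 for {fname!r}")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      size: int) -> np.ndarray:
    """Normal(mean, sd) truncated at 0 (seconds/counts cannot be negative)."""
    if sd == 0:
        return np.full(size, max(mean, 0.0))
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size,
                               random_state=rng)


def generate_behaviour_cohort(groups: Sequence[CohortGroup],
                              seed: int = 0) -> list[BehaviourTrial]:
    """Draw per-animal trials for each group spec; reproducible given seed."""
    if not groups:
        raise SigIOError("empty cohort specification")
    rng = np.random.default_rng(seed)
    trials = []
    counter = 0
    for g in groups:
        draws = {f: _truncated_normal(rng, m, s, g.n)
                 for f, (m, s) in g.params.items()}
        no_event = rng.random(g.n) < g.p_no_event
        for i in range(g.n):
            counter += 1
            kwargs = {f: float(v[i]) for f, v in draws.items()}
            if g.assay == "hyponeophagia":
                kwargs["event_observed"] = not bool(no_event[i])
                if no_event[i]:
                    kwargs.pop("latency", None)
            trials.append(BehaviourTrial(
                animal_id=f"m{counter:04d}", group_id=g.name, assay=g.assay,
                **kwargs))
    return trials


def default_behaviour_spec() -> list[CohortGroup]:
    """A three-arm novel-object-recognition cohort, 10 animals per group.

    Wild-type controls discriminate (D2 ≈ +0.33), untreated disease-model
    animals do not (D2 ≈ 0), and treated disease-model animals recover;
    plus a hyponeophagia arm where untreated animals often hit the 5-min
    maximal latency.
    """
    nor = lambda tn, tf: {"t_novel": (tn, 4.0), "t_familiar": (tf, 3.0)}
    return [
        CohortGroup("WT_vehicle", 10, "NOR", nor(20.0, 10.0)),
        CohortGroup("KO_vehicle", 10, "NOR", nor(15.0, 15.0)),
        CohortGroup("KO_treated", 10, "NOR", nor(20.0, 10.0)),
        CohortGroup("WT_vehicle_NSF", 10, "hyponeophagia",
                    {"latency": (60.0, 30.0)}),
        CohortGroup("KO_vehicle_NSF", 10, "hyponeophagia",
                    {"latency": (240.0, 80.0)}, p_no_event=0.3),
        CohortGroup("KO_treated_NSF", 10, "hyponeophagia",
                    {"latency": (90.0, 40.0)}),
    ]
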