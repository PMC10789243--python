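"""Behavioural endpoint formulas for mouse phenotyping assays.

Covers the endpoints used to profile fragile-X-model mice:

* discrimination index (D2) for novel object recognition (NOR), object
  location (OL) and social recognition (SR):
  ``D2 = (t_novel − t_familiar) / (t_novel + t_familiar)`` ∈ [−1, 1],
  positive when the animal prefers the novel stimulus (intact memory);
* the inclusion rule: an animal must explore the stimuli for a minimum
  total time (default 3 s) for its trial to enter the analysis;
* maximal-latency censoring for hyponeophagia (novelty-suppressed
  feeding): an animal that never drinks within the test receives the
  test duration (default 300 s) as a censored latency;
* per-group summary tables (n, mean, SD, SEM) ready for any stats
  package.  SD uses the n−1 denominator and SEM = SD/√n.

Inferential statistics (ANOVA families, post hoc tests) are deliberately
not implemented here — the tidy endpoint tables this module emits are the
hand-off point to standard tooling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .sigio import SigIOError

logger = logging.getLogger(__name__)

__all__ = ["BehaviourTrial", "EndpointRecord", "d2_score", "apply_inclusion",
           "cap_latency", "compute_endpoints", "summarize_groups",
           "read_trials", "trials_frame", "endpoints_frame"]

ASSAYS = ("NOR", "OL", "SR", "hyponeophagia", "open_field", "grooming",
          "aggression", "cFC")
D2_ASSAYS = ("NOR", "OL", "SR")

DEFAULT_MIN_EXPLORATION = 3.0   # seconds, total over both stimuli
DEFAULT_TEST_DURATION = 300.0   # seconds; 5-min hyponeophagia test


@dataclass(frozen=True)
class BehaviourTrial:
    """One animal's raw measurements for one assay.

    Only the fields relevant to the assay are populated: ``t_novel`` /
    ``t_familiar`` for the D2 assays, ``latency`` (+ ``event_observed``)
    for hyponeophagia, ``raw_value`` for the rest (distance in cm,
    grooming seconds, mount count, % freezing).
    """

    animal_id: str
    group_id: str
    assay: str
    t_novel: float | None = None
    t_familiar: float | None = None
    latency: float | None = None
    event_observed: bool | None = None
    raw_value: float | None = None

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise SigIOError(f"unknown assay {self.assay!r}; expected one of {ASSAYS}")
        for name in ("t_novel", "t_familiar", "latency"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise SigIOError(
                    f"animal {self.animal_id!r}: {name} must be a finite "
                    f"non-negative time, got {v!r}"
                )


@dataclass(frozen=True)
class EndpointRecord:
    """An analysis-ready endpoint for one animal, with inclusion/censoring."""

    animal_id: str
    group_id: str
    assay: str
    endpoint_value: float | None
    included: bool
    censored: bool = False


def d2_score(t_novel: float, t_familiar: float) -> float:
    """Discrimination index (t_novel − t_familiar)/(t_novel + t_familiar).

    Serves NOR (novel vs familiar object), SR (novel vs familiar mouse)
    and OL (novel vs familiar location).  Requires positive total
    exploration; a zero total is screened out upstream by the inclusion
    rule, so here it is an error.
    """
    total = t_novel + t_familiar
    if total <= 0:
        raise SigIOError("zero total exploration time: D2 undefined")
    return (t_novel - t_familiar) / total


def apply_inclusion(trial: BehaviourTrial,
                    min_exploration: float = DEFAULT_MIN_EXPLORATION,
                    ) -> EndpointRecord:
    """Apply the minimum-exploration inclusion rule to a D2-assay trial.

    The animal is included when its total exploration time
    (novel + familiar) reaches ``min_exploration`` seconds (boundary
    inclusive); the D2 endpoint is computed only for included animals.
    """
    if trial.assay not in D2_ASSAYS:
        raise SigIOError(f"inclusion rule applies to {D2_ASSAYS}, not {trial.assay!r}")
    if trial.t_novel is None or trial.t_familiar is None:
        raise SigIOError(f"animal {trial.animal_id!r}: exploration times missing")
    included = (trial.t_novel + trial.t_familiar) >= min_exploration
    value = d2_score(trial.t_novel, trial.t_familiar) if included else None
    return EndpointRecord(trial.animal_id, trial.group_id, trial.assay,
                          value, included)


def cap_latency(latency: float | None,
                test_duration: float = DEFAULT_TEST_DURATION,
                censor_at_boundary: bool = False) -> tuple[float, bool]:
    """Cap a latency at the test duration; no event ⇒ maximal, censored.

    ``latency=None`` means the event never occurred within the test: the
    animal receives the maximal latency score (the test duration) and is
    marked censored.  A recorded latency beyond the duration is likewise
    capped and censored.  A latency exactly at the test end is, by the
    default convention, an observed event; set ``censor_at_boundary`` to
    treat it as censored instead.
    """
    if test_duration <= 0:
        raise SigIOError("test duration must be positive")
    if latency is None:
        return test_duration, True
    if latency < 0:
        raise SigIOError(f"negative latency: {latency!r}")
    if latency > test_duration:
        return test_duration, True
    if latency == test_duration and censor_at_boundary:
        return test_duration, True
    return float(latency), False


def compute_endpoints(trials: Iterable[BehaviourTrial],
                      min_exploration: float = DEFAULT_MIN_EXPLORATION,
                      test_duration: float = DEFAULT_TEST_DURATION,
                      censor_at_boundary: bool = False,
                      ) -> list[EndpointRecord]:
    """Dispatch each trial to its assay's endpoint rule."""
    records = []
    for trial in trials:
        if trial.assay in D2_ASSAYS:
            records.append(apply_inclusion(trial, min_exploration))
        elif trial.assay == "hyponeophagia":
            latency = trial.latency
            if trial.event_observed is False:
                latency = None
            value, censored = cap_latency(latency, test_duration,
                                          censor_at_boundary)
            records.append(EndpointRecord(trial.animal_id, trial.group_id,
                                          trial.assay, value, True, censored))
        else:
            if trial.raw_value is None:
                raise SigIOError(
                    f"animal {trial.animal_id!r}: {trial.assay} needs raw_value")
            records.append(EndpointRecord(trial.animal_id, trial.group_id,
                                          trial.assay, float(trial.raw_value),
                                          True))
    return records


def summarize_groups(records: Sequence[EndpointRecord]) -> pd.DataFrame:
    """Per-(group, assay) endpoint summary: n_included, n_excluded, mean, SD, SEM.

    Rows appear in stable first-seen group order.  SD uses n−1; a
    single-animal group gets NaN SD/SEM and is flagged in the ``note``
    column; a group with zero included animals gets a warning row with no
    statistics.
    """
    rows = []
    order: list[tuple[str, str]] = []
    by_group: dict[tuple[str, str], list[EndpointRecord]] = {}
    for rec in records:
        key = (rec.group_id, rec.assay)
        if key not in by_group:
            by_group[key] = []
            order.append(key)
        by_group[key].append(rec)

    for group_id, assay in order:
        recs = by_group[(group_id, assay)]
        values = np.array([r.endpoint_value for r in recs if r.included],
                          dtype=float)
        n_inc, n_exc = values.size, len(recs) - values.size
        if n_inc == 0:
            logger.warning("group %s / %s: no included animals", group_id, assay)
            rows.append((group_id, assay, 0, n_exc, np.nan, np.nan, np.nan,
                         "no included animals"))
            continue
        mean = float(values.mean())
        if n_inc == 1:
            rows.append((group_id, assay, 1, n_exc, mean, np.nan, np.nan,
                         "single animal: SD/SEM undefined"))
            continue
        sd = float(values.std(ddof=1))
        rows.append((group_id, assay, n_inc, n_exc, mean, sd,
                     sd / math.sqrt(n_inc), ""))
    return pd.DataFrame(rows, columns=["group_id", "assay", "n_included",
                                       "n_excluded", "mean", "sd", "sem",
                                       "note"])


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

_TRIAL_COLUMNS = ["animal_id", "group_id", "assay", "t_novel", "t_familiar",
                  "latency", "event_observed", "raw_value"]


def read_trials(path: str | Path) -> list[BehaviourTrial]:
    """Read per-trial TSV (see ``_TRIAL_COLUMNS``); blank cells mean absent."""
    frame = pd.read_csv(path, sep="\t",
                        dtype={"animal_id": str, "group_id": str, "assay": str})
    missing = set(_TRIAL_COLUMNS) - set(frame.columns)
    if missing:
        raise SigIOError(f"{path}: missing columns {sorted(missing)}")
    trials = []
    for row in frame.itertuples(index=False):
        def opt(v):
            return None if pd.isna(v) else float(v)
        event = row.event_observed
        trials.append(BehaviourTrial(
            animal_id=row.animal_id, group_id=row.group_id, assay=row.assay,
            t_novel=opt(row.t_novel), t_familiar=opt(row.t_familiar),
            latency=opt(row.latency),
            event_observed=None if pd.isna(event) else bool(event),
            raw_value=opt(row.raw_value)))
    return trials


def trials_frame(trials: Sequence[BehaviourTrial]) -> pd.DataFrame:
    return pd.DataFrame([{c: getattr(t, c) for c in _TRIAL_COLUMNS}
                         for t in trials], columns=_TRIAL_COLUMNS)


def endpoints_frame(records: Sequence[EndpointRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "animal_id": [r.animal_id for r in records],
            "group_id": [r.group_id for r in records],
            "assay": [r.assay for r in records],
            "endpoint_value": [r.endpoint_value for r in records],
            "included": [r.included for r in records],
            "censored": [r.censored for r in records],
        }
    )
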