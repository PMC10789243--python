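import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from combopredict.behaviour import (BehaviourTrial, EndpointRecord,
                                    apply_inclusion, cap_latency,
                                    compute_endpoints, d2_score, read_trials,
                                    summarize_groups, trials_frame)
from combopredict.sigio import SigIOError

pos_times = st.floats(0.01, 600, allow_nan=False)


class TestD2Score:
    @pytest.mark.parametrize("t_novel, t_familiar, expected", [
        (30.0, 10.0, 0.5),   # printed-formula substitution
        (12.0, 12.0, 0.0),   # equal exploration: no discrimination
        (20.0, 0.0, 1.0),    # exclusive novel preference
        (0.0, 20.0, -1.0),
        (2.0, 1.0, 1 / 3),
    ])
    def test_formula(self, t_novel, t_familiar, expected):
        assert d2_score(t_novel, t_familiar) == pytest.approx(expected)

    def test_zero_total_exploration_is_error(self):
        with pytest.raises(SigIOError, match="zero total"):
            d2_score(0.0, 0.0)

    @settings(deadline=None)
    @given(pos_times, pos_times)
    def test_antisymmetry_and_bounds(self, a, b):
        d = d2_score(a, b)
        assert -1.0 <= d <= 1.0
        assert d == pytest.approx(-d2_score(b, a))


def nor_trial(t_novel, t_familiar, animal="m1"):
    return BehaviourTrial(animal, "grp", "NOR",
                          t_novel=t_novel, t_familiar=t_familiar)


class TestInclusionRule:
    def test_below_threshold_excluded_without_endpoint(self):
        rec = apply_inclusion(nor_trial(1.0, 1.0))
        assert not rec.included and rec.endpoint_value is None

    def test_boundary_total_of_three_seconds_included(self):
        rec = apply_inclusion(nor_trial(2.0, 1.0))
        assert rec.included and rec.endpoint_value == pytest.approx(1 / 3)

    def test_zero_exploration_excluded_not_an_error(self):
        rec = apply_inclusion(nor_trial(0.0, 0.0))
        assert not rec.included and rec.endpoint_value is None

    def test_threshold_is_configurable(self):
        assert apply_inclusion(nor_trial(1.0, 1.0), min_exploration=2.0).included

    def test_only_d2_assays_accepted(self):
        trial = BehaviourTrial("m1", "grp", "open_field", raw_value=100.0)
        with pytest.raises(SigIOError):
            apply_inclusion(trial)


class TestCapLatency:
    def test_no_event_gets_maximal_censored_score(self):
        assert cap_latency(None, 300.0) == (300.0, True)

    def test_observed_latency_passes_through(self):
        assert cap_latency(120.0, 300.0) == (120.0, False)

    def test_boundary_latency_observed_by_default(self):
        assert cap_latency(300.0, 300.0) == (300.0, False)
        assert cap_latency(300.0, 300.0, censor_at_boundary=True) == (300.0, True)

    def test_over_duration_capped_and_censored(self):
        assert cap_latency(301.0, 300.0) == (300.0, True)

    def test_negative_latency_rejected(self):
        with pytest.raises(SigIOError, match="negative"):
            cap_latency(-1.0)

    @settings(deadline=None)
    @given(st.one_of(st.none(), st.floats(0, 600, allow_nan=False)))
    def test_idempotent_on_the_capped_value(self, latency):
        value, _ = cap_latency(latency, 300.0)
        again, _ = cap_latency(value, 300.0)
        assert again == value and 0.0 <= value <= 300.0


class TestSummarizeGroups:
    def records(self, values, group="g1", assay="NOR", included=None):
        included = included or [True] * len(values)
        return [EndpointRecord(f"m{i}", group, assay, v if inc else None, inc)
                for i, (v, inc) in enumerate(zip(values, included))]

    def test_closed_form_mean_sd_sem(self):
        table = summarize_groups(self.records([0.0, 0.5, 1.0]))
        row = table.iloc[0]
        assert row["mean"] == pytest.approx(0.5)
        assert row["sd"] == pytest.approx(0.5)
        assert row["sem"] == pytest.approx(0.5 / math.sqrt(3))
        assert row["n_included"] == 3

    def test_single_animal_group_flagged(self):
        row = summarize_groups(self.records([0.3])).iloc[0]
        assert np.isnan(row["sd"]) and np.isnan(row["sem"])
        assert "single animal" in row["note"]

    def test_excluded_animals_do_not_alter_mean(self):
        with_excluded = self.records([0.0, 0.5, 1.0, 99.0],
                                     included=[True, True, True, False])
        row = summarize_groups(with_excluded).iloc[0]
        assert row["mean"] == pytest.approx(0.5)
        assert row["n_excluded"] == 1

    def test_zero_included_gives_warning_row(self, caplog):
        recs = self.records([1.0], included=[False])
        with caplog.at_level("WARNING"):
            table = summarize_groups(recs)
        row = table.iloc[0]
        assert row["n_included"] == 0 and np.isnan(row["mean"])
        assert "no included animals" in row["note"]

    def test_row_count_equals_distinct_groups(self):
        recs = (self.records([0.1, 0.2], group="a")
                + self.records([0.3], group="b")
                + self.records([0.4], group="c", assay="OL"))
        assert summarize_groups(recs).shape[0] == 3


class TestEndpointDispatchAndIO:
    def test_compute_endpoints_routes_by_assay(self):
        trials = [
            nor_trial(30.0, 10.0),
            BehaviourTrial("m2", "grp", "hyponeophagia", latency=400.0,
                           event_observed=True),
            BehaviourTrial("m3", "grp", "hyponeophagia", event_observed=False),
            BehaviourTrial("m4", "grp", "grooming", raw_value=55.0),
        ]
        recs = compute_endpoints(trials)
        assert recs[0].endpoint_value == pytest.approx(0.5)
        assert (recs[1].endpoint_value, recs[1].censored) == (300.0, True)
        assert (recs[2].endpoint_value, recs[2].censored) == (300.0, True)
        assert recs[3].endpoint_value == 55.0 and not recs[3].censored

    def test_trials_tsv_round_trip(self, tmp_path):
        trials = [nor_trial(30.0, 10.0),
                  BehaviourTrial("m2", "grp", "hyponeophagia", latency=120.0,
                                 event_observed=True)]
        path = tmp_path / "trials.tsv"
        trials_frame(trials).to_csv(path, sep="\t", index=False)
        back = read_trials(path)
        assert back[0].t_novel == 30.0 and back[0].assay == "NOR"
        assert back[1].latency == 120.0 and back[1].event_observed is True

    def test_negative_time_rejected(self):
        with pytest.raises(SigIOError, match="non-negative"):
            BehaviourTrial("m1", "g", "NOR", t_novel=-1.0, t_familiar=1.0)

    def test_unknown_assay_rejected(self):
        with pytest.raises(SigIOError, match="assay"):
            BehaviourTrial("m1", "g", "maze", raw_value=1.0)
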