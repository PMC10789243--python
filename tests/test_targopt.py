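import pytest

from combopredict import synthetic as syn
from combopredict.sigio import SigIOError
from combopredict.targopt import (TargetCatalog, pareto_front,
                                  read_target_catalog, targopt_rank_pairs,
                                  targopt_score)

DIS = {"T1": -1, "T2": -1}


def eng(*pairs):
    return frozenset(pairs)


class TestScore:
    def test_joint_full_coverage_no_off_targets(self):
        s = targopt_score(eng(("T1", -1)), eng(("T2", -1)), DIS, 1.0, 0.5)
        assert (s.on_count, s.off_count, s.score) == (2, 0, 2.0)

    def test_wrong_direction_counts_as_off_target(self):
        s = targopt_score(eng(("T1", +1)), eng(), DIS, 1.0, 0.5)
        assert (s.on_count, s.off_count, s.score) == (0, 1, -0.5)

    def test_double_coverage_counted_once(self):
        s = targopt_score(eng(("T1", -1)), eng(("T1", -1)), DIS, 1.0, 0.5)
        assert (s.on_count, s.off_count) == (1, 0)

    def test_non_disease_target_is_off_target(self):
        s = targopt_score(eng(("T1", -1), ("X9", +1)), eng(), DIS, 1.0, 0.5)
        assert (s.on_count, s.off_count, s.score) == (1, 1, 0.5)

    def test_symmetry(self):
        a, b = eng(("T1", -1), ("X1", +1)), eng(("T2", -1))
        sa = targopt_score(a, b, DIS)
        sb = targopt_score(b, a, DIS)
        assert (sa.on_count, sa.off_count, sa.score) == \
            (sb.on_count, sb.off_count, sb.score)

    def test_malformed_direction_is_error(self):
        with pytest.raises(SigIOError, match="direction"):
            targopt_score(eng(("T1", 2)), eng(), DIS)

    def test_negative_weights_rejected(self):
        with pytest.raises(SigIOError):
            targopt_score(eng(), eng(), DIS, alpha=-1.0)


def random_catalog(rng_seed, n_drugs, n_targets):
    import numpy as np
    rng = np.random.default_rng(rng_seed)
    targets = [f"T{i}" for i in range(n_targets)]
    drugs = {}
    for d in range(n_drugs):
        k = int(rng.integers(0, n_targets + 1))
        chosen = rng.choice(targets, size=k, replace=False)
        drugs[f"d{d}"] = frozenset(
            (t, int(rng.choice([-1, 1]))) for t in chosen)
    disease = {t: int(rng.choice([-1, 1]))
               for t in targets if rng.random() < 0.5}
    return TargetCatalog(drugs, disease)


class TestRankPairs:
    def test_matches_bruteforce_on_toy_catalogs(self):
        """Exhaustive recomputation oracle on catalogs with <=6 drugs,
        <=8 targets: for every pair, recount on/off targets from first
        principles and check the returned ordering obeys the sort key."""
        for seed in range(10):
            cat = random_catalog(seed, n_drugs=6, n_targets=8)
            scores = targopt_rank_pairs(cat, alpha=1.0, beta=0.5)
            assert len(scores) == 15
            for s in scores:
                a, b = s.pair
                union = set(cat.drug_targets[a]) | set(cat.drug_targets[b])
                on = {t for t, d in union if cat.disease_targets.get(t) == d}
                off = {t for t, d in union if cat.disease_targets.get(t) != d}
                assert s.on_count == len(on) and s.off_count == len(off)
                assert s.score == pytest.approx(len(on) - 0.5 * len(off))
            keys = [(-s.score, -s.on_count, s.pair) for s in scores]
            assert keys == sorted(keys)

    def test_beta_zero_ranking_ignores_off_targets(self):
        cat = TargetCatalog({
            "a": eng(("T1", -1)),
            "b": eng(("T2", -1), ("X1", +1), ("X2", +1)),
            "c": eng(("T2", -1)),
        }, dict(DIS))
        scores = targopt_rank_pairs(cat, alpha=1.0, beta=0.0)
        by_pair = {s.pair: s.score for s in scores}
        # off-target load of b is invisible at beta=0
        assert by_pair[("a", "b")] == by_pair[("a", "c")] == 2.0

    def test_absent_drug_named_in_error(self):
        cat = random_catalog(0, 3, 4)
        with pytest.raises(SigIOError, match="ghost"):
            targopt_rank_pairs(cat, drugs=["d0", "ghost"])

    def test_planted_catalog_recovered(self):
        cat = syn.generate_target_catalog(
            n_drugs=12, n_disease_targets=5, n_decoy_targets=6,
            planted_pair=("drugA", "drugB"), seed=3)
        top = targopt_rank_pairs(cat, alpha=1.0, beta=0.5)[0]
        assert top.pair == ("drugA", "drugB")
        assert top.off_count == 0
        assert top.on_count == 5

    def test_monotonicity_in_targets(self):
        """Adding an off-target never raises a score (beta>0); adding a
        correctly-directed disease target never lowers it (alpha>0)."""
        for seed in range(5):
            cat = random_catalog(seed + 50, 5, 6)
            base = {s.pair: s.score for s in targopt_rank_pairs(cat)}
            drug = sorted(cat.drug_targets)[0]
            worse = dict(cat.drug_targets)
            worse[drug] = worse[drug] | {("DECOY_NEW", +1)}
            worse_scores = {s.pair: s.score for s in targopt_rank_pairs(
                TargetCatalog(worse, cat.disease_targets))}
            for pair, score in worse_scores.items():
                if drug in pair:
                    assert score <= base[pair]
            if cat.disease_targets:
                t, d = next(iter(cat.disease_targets.items()))
                better = dict(cat.drug_targets)
                better[drug] = better[drug] | {(t, d)}
                better_scores = {s.pair: s.score for s in targopt_rank_pairs(
                    TargetCatalog(better, cat.disease_targets))}
                for pair, score in better_scores.items():
                    if drug in pair:
                        assert score >= base[pair]


class TestParetoFront:
    def test_front_members_are_non_dominated(self):
        cat = random_catalog(4, 6, 8)
        scores = targopt_rank_pairs(cat)
        front = pareto_front(scores)
        assert front
        by_pair = {s.pair: s for s in scores}
        for p in front:
            s = by_pair[p]
            for o in scores:
                assert not ((o.on_count >= s.on_count and
                             o.off_count <= s.off_count) and
                            (o.on_count > s.on_count or
                             o.off_count < s.off_count))


class TestCatalogIO:
    def test_tsv_round_trip(self, tmp_path):
        (tmp_path / "targets.tsv").write_text(
            "drug_id\ttarget_id\tdirection\n"
            "ibudilast\tPDE4\t-1\nibudilast\tPDE10\t-1\n"
            "gaboxadol\tGABRD\t1\n")
        (tmp_path / "disease.tsv").write_text(
            "target_id\tdesired_direction\nPDE4\t-1\nPDE10\t-1\nGABRD\t1\n")
        cat = read_target_catalog(tmp_path / "targets.tsv",
                                  tmp_path / "disease.tsv")
        s = targopt_rank_pairs(cat)[0]
        assert s.pair == ("gaboxadol", "ibudilast")
        assert (s.on_count, s.off_count) == (3, 0)
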