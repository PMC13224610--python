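import numpy as np
import pytest
from scipy import stats as sps

from g4shift.intervals import GenomeDef, GenomicInterval, IntervalSet, ValidationError
from g4shift.stats import (
    ContingencyTable2x2,
    build_contingency,
    distance_profile,
    fold_change_pseudocount,
    kruskal_dunn,
    pearson_chi_square,
    percent_within,
    rank_sum_test,
    shuffled_control_percent,
    wilcoxon_one_sample,
)

import oracles


@pytest.fixture
def genome():
    return GenomeDef.from_pairs([("chr1", 10_000)])


def points(genome, positions):
    return IntervalSet(
        (GenomicInterval("chr1", p, p + 1) for p in positions), genome, "events"
    )


class TestPercentWithin:
    def test_basic_arithmetic(self, genome):
        events = points(genome, range(12))
        feats = IntervalSet([GenomicInterval("chr1", 0, 3)], genome, "features")
        assert percent_within(events, feats, 0) == 25.0

    def test_empty_features_zero(self, genome):
        events = points(genome, [5])
        assert percent_within(events, IntervalSet((), genome, "features"), 5) == 0.0

    def test_full_coverage_hundred(self, genome):
        events = points(genome, [1, 2, 3])
        feats = IntervalSet([GenomicInterval("chr1", 0, 10_000)], genome, "features")
        assert percent_within(events, feats, 0) == 100.0

    def test_empty_events_error(self, genome):
        with pytest.raises(ValidationError):
            percent_within(IntervalSet((), genome), points(genome, [1]), 0)


class TestChiSquare:
    def test_closed_form_example(self):
        res = pearson_chi_square(ContingencyTable2x2(((10, 90), (30, 70))))
        assert res.statistic == pytest.approx(12.5, abs=1e-9)
        assert res.expected[0][0] == pytest.approx(20.0)
        assert res.residuals[1][0] == pytest.approx(2.236, abs=5e-4)
        assert res.df == 1

    def test_null_table(self):
        res = pearson_chi_square(ContingencyTable2x2(((20, 80), (20, 80))))
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)
        assert all(r == 0 for row in res.residuals for r in row)

    def test_row_swap_negates_residuals(self):
        a = pearson_chi_square(ContingencyTable2x2(((10, 90), (30, 70))))
        b = pearson_chi_square(ContingencyTable2x2(((30, 70), (10, 90))))
        assert a.statistic == pytest.approx(b.statistic)
        for ra, rb in zip(np.ravel(a.residuals), np.ravel(np.asarray(b.residuals)[::-1])):
            assert ra == pytest.approx(rb)

    def test_statistic_equals_sum_of_squared_residuals_random(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            o = rng.integers(1, 500, size=(2, 2))
            res = pearson_chi_square(ContingencyTable2x2(tuple(map(tuple, o))))
            assert res.statistic == pytest.approx(
                float(np.sum(np.asarray(res.residuals) ** 2)), rel=1e-12
            )
            # closed form N(ad-bc)^2 / (marginal product)
            a, b, c, d = o.ravel()
            n = o.sum()
            closed = n * (a * d - b * c) ** 2 / (
                (a + b) * (c + d) * (a + c) * (b + d)
            )
            assert res.statistic == pytest.approx(closed, abs=1e-9)
            # independent route: scipy without continuity correction
            stat, p, _, _ = sps.chi2_contingency(o, correction=False)
            assert res.statistic == pytest.approx(stat)
            assert res.p_value == pytest.approx(p)

    def test_zero_marginal_degenerate(self):
        with pytest.raises(ValidationError):
            pearson_chi_square(ContingencyTable2x2(((0, 90), (0, 70))))


class TestContingencyConstruction:
    def test_bookkeeping(self, genome):
        a = points(genome, range(100))
        b = points(genome, range(100))
        feats = IntervalSet([GenomicInterval("chr1", 0, 10)], genome, "features")
        t = build_contingency({"par": a, "ko": b}, feats, 0)
        assert t.observed == ((10, 90), (10, 90))

    def test_associated_monotone_in_w(self, genome):
        a = points(genome, range(0, 1000, 10))
        b = points(genome, range(5, 1000, 10))
        feats = IntervalSet([GenomicInterval("chr1", 100, 150)], genome, "features")
        prev = -1
        for w in (0, 5, 20, 100):
            t = build_contingency({"a": a, "b": b}, feats, w)
            assoc = t.observed[0][0] + t.observed[1][0]
            assert assoc >= prev
            prev = assoc


class TestFoldChange:
    @pytest.mark.parametrize("obs,ctrl,expected", [(0, 0, 1.0), (9, 4, 2.0), (7, 7, 1.0)])
    def test_pseudocount_rule(self, obs, ctrl, expected):
        assert fold_change_pseudocount(obs, ctrl) == expected


class TestRankTests:
    def test_mannwhitney_disjoint_three_vs_three(self):
        assert rank_sum_test([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    def test_mannwhitney_matches_enumeration(self):
        rng = np.random.default_rng(8)
        for n in (2, 3, 5, 8):
            for m in (2, 4, 8):
                x = rng.normal(size=n).tolist()
                y = (rng.normal(size=m) + 0.5).tolist()
                assert rank_sum_test(x, y) == pytest.approx(
                    oracles.enum_mannwhitney_p(x, y), abs=1e-12
                )

    def test_mannwhitney_shift_invariant(self):
        x, y = [1.0, 2.5, 3.1], [2.0, 4.0, 5.5]
        assert rank_sum_test(x, y) == rank_sum_test([v + 7 for v in x], [v + 7 for v in y])

    def test_wilcoxon_all_above(self):
        p = wilcoxon_one_sample([1.2, 1.3, 1.1, 1.4, 1.25], 1.0)
        assert p == pytest.approx(0.0625)

    def test_wilcoxon_matches_enumeration(self):
        rng = np.random.default_rng(9)
        for n in (3, 5, 8):
            x = (rng.normal(size=n) + 0.3).tolist()
            assert wilcoxon_one_sample(x, 0.0) == pytest.approx(
                oracles.enum_wilcoxon_p(x, 0.0), abs=1e-12
            )

    def test_wilcoxon_scale_invariant(self):
        x = [0.5, 1.5, -0.25, 2.0]
        assert wilcoxon_one_sample(x) == pytest.approx(
            wilcoxon_one_sample([10 * v for v in x])
        )

    def test_wilcoxon_degenerate(self):
        with pytest.raises(ValidationError):
            wilcoxon_one_sample([2.0, 2.0], 2.0)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValidationError):
            rank_sum_test([], [1.0])


class TestKruskalDunn:
    def test_ordered_groups(self):
        groups = {
            "low": [1.0, 2.0, 3.0, 4.0],
            "mid": [10.0, 11.0, 12.0, 13.0],
            "high": [20.0, 21.0, 22.0, 23.0],
        }
        h, p, pairs = kruskal_dunn(groups)
        assert p < 0.01
        zmap = {(d["group_1"], d["group_2"]): d["z"] for d in pairs}
        assert zmap[("low", "mid")] < 0 and zmap[("low", "high")] < 0
        assert abs(zmap[("low", "high")]) > abs(zmap[("low", "mid")])

    def test_identical_groups_null(self):
        g = {k: [1.0, 2.0, 3.0, 4.0, 5.0] for k in "abc"}
        h, p, pairs = kruskal_dunn(g)
        assert p > 0.9
        assert all(d["p_adjusted"] > 0.9 for d in pairs)

    def test_label_permutation_consistency(self):
        groups = {"a": [1.0, 2.0], "b": [5.0, 6.0], "c": [9.0, 10.0]}
        h1, p1, pairs1 = kruskal_dunn(groups)
        h2, p2, pairs2 = kruskal_dunn({"c": groups["c"], "a": groups["a"], "b": groups["b"]})
        assert h1 == pytest.approx(h2) and p1 == pytest.approx(p2)
        z1 = {frozenset((d["group_1"], d["group_2"])): abs(d["z"]) for d in pairs1}
        z2 = {frozenset((d["group_1"], d["group_2"])): abs(d["z"]) for d in pairs2}
        for k in z1:
            assert z1[k] == pytest.approx(z2[k])

    def test_requires_three_groups(self):
        with pytest.raises(ValidationError):
            kruskal_dunn({"a": [1.0], "b": [2.0]})


class TestShuffledControlAndProfiles:
    def test_determinism(self, genome):
        events = points(genome, range(0, 1000, 7))
        feats = IntervalSet([GenomicInterval("chr1", 0, 100)], genome, "features")
        a = shuffled_control_percent(events, feats, genome, None, 0, 1, seed=3)
        b = shuffled_control_percent(events, feats, genome, None, 0, 1, seed=3)
        assert a == b

    def test_exclusion_covering_features_forces_zero(self, genome):
        events = points(genome, range(0, 500, 5))
        feats = IntervalSet([GenomicInterval("chr1", 100, 200)], genome, "features")
        excl = IntervalSet([GenomicInterval("chr1", 100, 200)], genome, "exclusion")
        pcts = shuffled_control_percent(events, feats, genome, excl, 0, 10, seed=1)
        assert all(p == 0.0 for p in pcts)

    def test_profile_planted_inside(self, genome):
        feats = IntervalSet([GenomicInterval("chr1", 500, 600)], genome, "features")
        ev = {"s1": points(genome, range(510, 520)), "s2": points(genome, [555])}
        prof = distance_profile(ev, feats, list(range(0, 51, 5)))
        assert prof.percents[0][0] == 100.0 and prof.percents[1][0] == 100.0
        assert prof.counts[:, 1:].sum() == 0

    def test_profile_zero_events_in_range(self, genome):
        feats = IntervalSet([GenomicInterval("chr1", 9000, 9100)], genome, "features")
        ev = {"far": points(genome, [0])}
        prof = distance_profile(ev, feats, [0, 5, 10])
        assert prof.counts.sum() == 0
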