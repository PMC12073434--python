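"""Confusion counting, metrics, confidence intervals, and gated paired tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from mealdecomp.stats import (
    ConfusionCounts,
    GroundTruthLabels,
    anova_oneway,
    confusion,
    holm_adjust,
    mean_ci,
    metrics_from_confusion,
    paired_compare,
    pool_evaluators,
)


def _truth(compounds, basics, plan_id="p1"):
    return GroundTruthLabels.from_names("e1", plan_id, compounds, basics)


class TestConfusion:
    def test_perfect_prediction(self):
        c = confusion(_truth(["A", "B"], ["C"]), ["A", "B"])
        assert (c.tp, c.fp, c.fn, c.tn) == (2, 0, 0, 1)

    def test_empty_prediction_all_fn(self):
        c = confusion(_truth(["A", "B"], ["C", "D"]), [])
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 0, 2, 2)

    def test_hand_enumeration(self):
        c = confusion(_truth(["A", "B"], ["C", "D", "E"]), ["A", "C"])
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 2)

    def test_hallucinated_prediction_counts_fp(self, caplog):
        with caplog.at_level("WARNING"):
            c = confusion(_truth(["A"], ["B"]), ["A", "Pixie Dust"])
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 0, 1)
        assert any("not in plan" in r.message for r in caplog.records)

    def test_name_normalization_applies(self):
        c = confusion(_truth(["Chicken  Marsala"], []), ["chicken marsala"])
        assert c.tp == 1

    def test_conservation(self):
        truth = _truth(["A", "B", "C"], ["D", "E", "F", "G"])
        for predicted in ([], ["A"], ["A", "D", "E"], ["A", "B", "C", "D", "E", "F", "G"]):
            assert confusion(truth, predicted).total == 7


class TestMetricsFromConfusion:
    def test_hand_computation(self):
        m = metrics_from_confusion(ConfusionCounts(tp=3, fp=1, fn=1, tn=10))
        assert m.accuracy == pytest.approx(13 / 15)  # (tp + tn) / total
        assert m.precision == 0.75
        assert m.recall == 0.75
        assert m.f1 == 0.75

    def test_perfect(self):
        m = metrics_from_confusion(ConfusionCounts(tp=4, fp=0, fn=0, tn=6))
        assert m.accuracy == 1.0 and m.f1 == 1.0

    def test_zero_tp_with_fp_gives_zero_precision_and_f1(self):
        m = metrics_from_confusion(ConfusionCounts(tp=0, fp=2, fn=1, tn=5))
        assert m.precision == 0.0 and m.f1 == 0.0

    def test_no_compounds_no_claims_scores_one(self):
        m = metrics_from_confusion(ConfusionCounts(tp=0, fp=0, fn=0, tn=8))
        assert m.accuracy == 1.0 and m.f1 == 1.0

    def test_nothing_claimed_but_compounds_missed(self):
        m = metrics_from_confusion(ConfusionCounts(tp=0, fp=0, fn=3, tn=5))
        assert m.precision == 0.0 and m.recall == 0.0 and m.f1 == 0.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_confusion(ConfusionCounts(0, 0, 0, 0))

    @settings(max_examples=100, deadline=None)
    @given(
        tp=st.integers(0, 20), fp=st.integers(0, 20), fn=st.integers(0, 20), tn=st.integers(0, 20)
    )
    def test_ranges_and_f1_between_precision_and_recall(self, tp, fp, fn, tn):
        if tp + fp + fn + tn == 0:
            return
        m = metrics_from_confusion(ConfusionCounts(tp, fp, fn, tn))
        for v in (m.accuracy, m.precision, m.recall, m.f1):
            assert 0.0 <= v <= 1.0
        assert min(m.precision, m.recall) - 1e-12 <= m.f1 <= max(m.precision, m.recall) + 1e-12


class TestMeanCI:
    def test_all_equal_zero_width(self):
        mean, lo, hi = mean_ci([0.8, 0.8, 0.8])
        assert mean == pytest.approx(0.8)
        assert lo == mean == hi

    def test_two_values_match_closed_form(self):
        # mean 0.85, sd 0.0707..., sem sd/sqrt(2), t(0.975, df=1) = 12.7062
        mean, lo, hi = mean_ci([0.8, 0.9])
        sd = math.sqrt(((0.8 - 0.85) ** 2 + (0.9 - 0.85) ** 2) / 1)
        sem = sd / math.sqrt(2)
        tcrit = 12.706204736432095
        assert mean == pytest.approx(0.85)
        assert lo == pytest.approx(0.85 - tcrit * sem)
        assert hi == pytest.approx(0.85 + tcrit * sem)

    def test_wider_level_contains_narrower(self):
        rng = np.random.default_rng(1)
        values = rng.normal(0.8, 0.1, size=15).tolist()
        _, lo95, hi95 = mean_ci(values, 0.95)
        _, lo99, hi99 = mean_ci(values, 0.99)
        assert lo99 <= lo95 <= hi95 <= hi99

    def test_fewer_than_two_values_rejected(self):
        with pytest.raises(ValueError):
            mean_ci([0.5])


class TestPairedCompare:
    def test_identical_series_degenerate(self):
        result = paired_compare([0.8, 0.9, 0.7], [0.8, 0.9, 0.7])
        assert result.test_kind == "degenerate"
        assert result.p_value == 1.0
        assert result.normality_p is None

    def test_normal_differences_route_to_paired_t(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0.85, 0.05, size=15)
        b = a - rng.normal(0.03, 0.02, size=15)
        # oracle: this seeded sample passes Shapiro-Wilk at alpha 0.05
        assert sps.shapiro(a - b).pvalue > 0.05
        result = paired_compare(a, b)
        assert result.test_kind == "paired_t"
        expected = sps.ttest_rel(a, b)
        assert result.statistic == pytest.approx(float(expected.statistic))
        assert result.p_value == pytest.approx(float(expected.pvalue))
        assert result.n == 15

    def test_outlier_forces_wilcoxon(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0.8, 0.01, size=15)
        b = a.copy()
        b[0] -= 0.5  # one extreme difference breaks normality
        diffs_p = sps.shapiro(a - b).pvalue
        assert diffs_p <= 0.05
        result = paired_compare(a, b)
        assert result.test_kind == "wilcoxon"
        expected = sps.wilcoxon(a, b)
        assert result.statistic == pytest.approx(float(expected.statistic))

    def test_constant_nonzero_differences_fall_back_to_wilcoxon(self):
        a = [0.8, 0.7, 0.9, 0.6]
        b = [x - 0.1 for x in a]
        result = paired_compare(a, b)
        assert result.test_kind == "wilcoxon"
        assert result.normality_p is None

    def test_symmetry_up_to_sign(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0.8, 0.05, size=12)
        b = rng.normal(0.75, 0.05, size=12)
        ab = paired_compare(a, b)
        ba = paired_compare(b, a)
        assert ab.p_value == pytest.approx(ba.p_value)
        if ab.test_kind == "paired_t":
            assert ab.statistic == pytest.approx(-ba.statistic)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            paired_compare([1, 2], [2, 1])

    def test_misaligned_rejected(self):
        with pytest.raises(ValueError):
            paired_compare([1, 2, 3], [1, 2])


class TestPooling:
    def test_three_evaluators_of_15_pool_to_45(self):
        scores = {f"evaluator-{i}": [0.5 + 0.01 * j for j in range(15)] for i in range(3)}
        assert len(pool_evaluators(scores)) == 45

    def test_single_evaluator_identity(self):
        assert pool_evaluators({"e": [1.0, 2.0]}) == [1.0, 2.0]

    def test_order_of_evaluators_preserves_multiset(self):
        scores = {"b": [1.0, 2.0], "a": [3.0, 4.0]}
        assert sorted(pool_evaluators(scores)) == [1.0, 2.0, 3.0, 4.0]

    def test_mismatched_coverage_rejected(self):
        with pytest.raises(ValueError):
            pool_evaluators({"a": [1.0], "b": [1.0, 2.0]})


class TestAnova:
    def test_equal_means_give_f_zero(self):
        F, p = anova_oneway([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
        assert F == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_manual_sum_of_squares(self):
        groups = [[2.0, 3.0, 7.0], [6.0, 8.0, 4.0], [1.0, 2.0, 3.0]]
        flat = [v for g in groups for v in g]
        grand = sum(flat) / len(flat)
        ss_between = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
        ss_within = sum((v - sum(g) / len(g)) ** 2 for g in groups for v in g)
        df_b, df_w = len(groups) - 1, len(flat) - len(groups)
        f_manual = (ss_between / df_b) / (ss_within / df_w)
        F, p = anova_oneway(*groups)
        assert F == pytest.approx(f_manual)
        assert p == pytest.approx(float(sps.f.sf(f_manual, df_b, df_w)))

    def test_two_groups_reduce_to_squared_t(self):
        a = [1.0, 2.5, 3.0, 4.5]
        b = [2.0, 3.5, 5.0, 6.0]
        F, _ = anova_oneway(a, b)
        t = sps.ttest_ind(a, b, equal_var=True).statistic
        assert F == pytest.approx(t**2)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway([1.0], [2.0, 3.0])


def test_holm_adjustment_is_monotone_and_bounded():
    raw = [0.01, 0.04, 0.03, 0.20]
    adj = holm_adjust(raw)
    assert all(0 <= a <= 1 for a in adj)
    assert all(a >= r for a, r in zip(adj, raw))
    # hand check: sorted raw 0.01,0.03,0.04,0.20 -> 0.04, 0.09, 0.08->0.09, 0.20
    assert adj == pytest.approx([0.04, 0.09, 0.09, 0.20])
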