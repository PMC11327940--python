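"""Diagnostic metrics, kappa, contingency and rank tests, Bonferroni."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom

from lgedx.metrics import (
    ConfusionTable,
    TestMethod,
    bonferroni_threshold,
    cohen_kappa,
    compare_binary,
    compare_continuous,
    confusion_table,
    diagnostic_metrics,
    kappa_band,
    printed_threshold,
    round_percent,
)
from lgedx.classifiers import any_rv_lge
from lgedx.segments import Diagnosis, extract_features


class TestConfusionTable:
    def test_any_rv_on_fixture_reproduces_published_counts(self, fixture_cohort):
        preds = {p.id: any_rv_lge(extract_features(p)) for p in fixture_cohort}
        t = confusion_table(fixture_cohort, preds)
        assert (t.tp, t.fn, t.fp, t.tn) == (21, 34, 45, 32)

    def test_arvc_vs_dcm_restriction(self, fixture_cohort):
        preds = {p.id: any_rv_lge(extract_features(p)) for p in fixture_cohort}
        t = confusion_table(
            fixture_cohort, preds, restrict_to=[Diagnosis.ARVC, Diagnosis.DCM]
        )
        assert (t.fp, t.tn) == (4, 21)

    def test_empty_positive_prediction_set(self, fixture_cohort):
        preds = {p.id: False for p in fixture_cohort}
        t = confusion_table(fixture_cohort, preds)
        assert t.tp == 0 and t.fp == 0 and t.n == len(fixture_cohort)

    def test_missing_prediction_names_the_patient(self, fixture_cohort):
        preds = {p.id: True for p in fixture_cohort}
        missing = fixture_cohort.patients[0].id
        del preds[missing]
        with pytest.raises(KeyError, match=missing):
            confusion_table(fixture_cohort, preds)


class TestDiagnosticMetrics:
    @pytest.mark.parametrize(
        "cells,expected",
        [
            # published any-RV-LGE and Padua-RV 2x2s
            ((21, 45, 34, 32), (0.382, 0.416, 0.402, 0.318, 0.485)),
            ((20, 43, 35, 34), (0.364, 0.442, 0.409, 0.317, 0.493)),
        ],
    )
    def test_published_tables_give_published_proportions(self, cells, expected):
        tp, fp, fn, tn = cells
        m = diagnostic_metrics(ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn))
        got = (m.sensitivity, m.specificity, m.accuracy, m.ppv, m.npv)
        assert got == pytest.approx(expected, abs=5e-4)

    def test_perfect_classifier(self):
        m = diagnostic_metrics(ConfusionTable(tp=7, fp=0, fn=0, tn=9))
        assert (
            m.sensitivity == m.specificity == m.accuracy == m.ppv == m.npv == 1.0
        )

    def test_zero_margin_is_undefined_not_zero(self):
        m = diagnostic_metrics(ConfusionTable(tp=0, fp=0, fn=3, tn=5))
        assert m.ppv is None and m.ci["ppv"] is None
        assert m.sensitivity == 0.0

    @settings(max_examples=200, derandomize=True)
    @given(
        tp=st.integers(0, 50), fp=st.integers(0, 50),
        fn=st.integers(0, 50), tn=st.integers(0, 50),
    )
    def test_identities_on_random_tables(self, tp, fp, fn, tn):
        if tp + fp + fn + tn == 0:
            return
        m = diagnostic_metrics(ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn))
        if m.sensitivity is not None:
            assert m.sensitivity * (tp + fn) == pytest.approx(tp)
            lo, hi = m.ci["sensitivity"]
            assert lo <= m.sensitivity <= hi
        if m.sensitivity is not None and m.specificity is not None:
            n = tp + fp + fn + tn
            prev = (tp + fn) / n
            assert m.accuracy == pytest.approx(
                prev * m.sensitivity + (1 - prev) * m.specificity
            )

    def test_percent_rounding_is_half_up(self):
        assert round_percent(35 / 132) == 27  # 26.5% displays as 27
        assert round_percent(0.382) == 38


class TestCohenKappa:
    def test_identical_ratings_give_one(self):
        assert cohen_kappa(list("aabba"), list("aabba")) == 1.0

    def test_hand_computed_two_by_two_example(self):
        # p_o = 8/10, marginals 5/5 for both raters -> p_e = 0.5, kappa = 0.6
        a = ["+", "+", "-", "-", "+", "-", "+", "+", "-", "-"]
        b = ["+", "-", "-", "-", "+", "-", "+", "+", "+", "-"]
        assert cohen_kappa(a, b) == pytest.approx(0.6)
        assert kappa_band(0.6) == "moderate"

    def test_independent_ratings_drift_to_zero(self):
        rng = np.random.default_rng(7)
        a = rng.integers(0, 2, 5000).tolist()
        b = rng.integers(0, 2, 5000).tolist()
        assert abs(cohen_kappa(a, b)) < 0.05

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(3)
        a = rng.integers(0, 3, 200).tolist()
        b = (rng.integers(0, 3, 200)).tolist()
        assert cohen_kappa(a, b) == pytest.approx(cohen_kappa_score(a, b))

    def test_symmetry_and_relabeling_invariance(self):
        rng = np.random.default_rng(11)
        a = rng.integers(0, 3, 100).tolist()
        b = rng.integers(0, 3, 100).tolist()
        assert cohen_kappa(a, b) == pytest.approx(cohen_kappa(b, a))
        relabel = {0: "x", 1: "y", 2: "z"}
        assert cohen_kappa([relabel[v] for v in a], [relabel[v] for v in b]) == (
            pytest.approx(cohen_kappa(a, b))
        )

    def test_constant_identical_raters_flagged_kappa_one(self):
        with pytest.warns(UserWarning):
            assert cohen_kappa([1, 1, 1], [1, 1, 1]) == 1.0


def _fisher_oracle(k1, n1, k2, n2):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    total = n1 + n2
    successes = k1 + k2
    rv = hypergeom(total, successes, n1)
    p_obs = rv.pmf(k1)
    ks = np.arange(max(0, successes - n2), min(n1, successes) + 1)
    pmfs = rv.pmf(ks)
    return float(pmfs[pmfs <= p_obs * (1 + 1e-9)].sum())


class TestCompareBinary:
    def test_pearson_reproduces_padua_rv_p(self):
        res = compare_binary(20, 55, 43, 77, TestMethod.PEARSON_CHI2)
        assert res.p_value == pytest.approx(0.027, abs=5e-4)

    def test_yates_reproduces_any_rv_p(self):
        res = compare_binary(21, 55, 45, 77, TestMethod.YATES_CHI2)
        assert res.p_value == pytest.approx(0.034, abs=5e-4)

    def test_identical_groups_give_p_one_under_fisher(self):
        res = compare_binary(5, 20, 5, 20, TestMethod.FISHER_EXACT)
        assert res.p_value == pytest.approx(1.0)

    def test_degenerate_table_warns_p_one(self):
        with pytest.warns(UserWarning):
            res = compare_binary(0, 5, 0, 7)
        assert res.p_value == 1.0

    def test_auto_uses_fisher_for_small_expected_cells(self):
        res = compare_binary(1, 6, 5, 7)
        assert res.test_name is TestMethod.FISHER_EXACT

    @settings(max_examples=150, derandomize=True)
    @given(
        k1=st.integers(0, 15), extra1=st.integers(1, 10),
        k2=st.integers(0, 15), extra2=st.integers(1, 10),
    )
    def test_fisher_matches_enumeration(self, k1, extra1, k2, extra2):
        n1, n2 = k1 + extra1, k2 + extra2
        if k1 + k2 == 0 or (n1 - k1) + (n2 - k2) == 0:
            return
        res = compare_binary(k1, n1, k2, n2, TestMethod.FISHER_EXACT)
        assert res.p_value == pytest.approx(_fisher_oracle(k1, n1, k2, n2), rel=1e-6)

    @settings(max_examples=150, derandomize=True)
    @given(
        k1=st.integers(0, 30), extra1=st.integers(1, 30),
        k2=st.integers(0, 30), extra2=st.integers(1, 30),
    )
    def test_pearson_chi2_equals_squared_two_proportion_z(self, k1, extra1, k2, extra2):
        n1, n2 = k1 + extra1, k2 + extra2
        if k1 + k2 == 0 or (n1 - k1) + (n2 - k2) == 0:
            return
        res = compare_binary(k1, n1, k2, n2, TestMethod.PEARSON_CHI2)
        p1, p2, p = k1 / n1, k2 / n2, (k1 + k2) / (n1 + n2)
        z2 = (p1 - p2) ** 2 / (p * (1 - p) * (1 / n1 + 1 / n2))
        assert res.statistic == pytest.approx(z2, rel=1e-9)


class TestCompareContinuous:
    def test_identical_samples_give_p_one(self):
        with pytest.warns(UserWarning):
            res = compare_continuous([[3, 3, 3], [3, 3, 3]])
        assert res.p_value == 1.0

    def test_fully_separated_small_samples_exact_enumeration(self):
        # U = 0; one-sided exact p = 1/C(6,3) = 0.05, two-sided doubles it
        res = compare_continuous([[1, 2, 3], [4, 5, 6]], TestMethod.MANN_WHITNEY)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)

    def test_kruskal_wallis_type_I_error_rate(self):
        rng = np.random.default_rng(42)
        rejections = 0
        trials = 1000
        for _ in range(trials):
            groups = [rng.standard_normal(12) for _ in range(3)]
            if compare_continuous(groups, TestMethod.KRUSKAL_WALLIS).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / trials <= 0.07

    def test_needs_two_nonempty_groups(self):
        with pytest.raises(ValueError):
            compare_continuous([[1, 2]])
        with pytest.raises(ValueError):
            compare_continuous([[1, 2], []])


class TestBonferroni:
    def test_threshold_is_alpha_over_m(self):
        assert bonferroni_threshold(0.05, 1) == 0.05
        assert bonferroni_threshold(0.05, 12) == pytest.approx(0.05 / 12)

    @pytest.mark.parametrize("m,printed", [(12, 0.004), (15, 0.003), (26, 0.002)])
    def test_printed_thresholds_match_table_footnotes(self, m, printed):
        assert printed_threshold(0.05, m) == printed

    def test_m_zero_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)

    def test_significance_flag(self):
        res = compare_binary(20, 55, 43, 77, TestMethod.PEARSON_CHI2, m_comparisons=12)
        assert not res.significant_after_bonferroni
        res1 = compare_binary(20, 55, 43, 77, TestMethod.PEARSON_CHI2, m_comparisons=1)
        assert res1.significant_after_bonferroni
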