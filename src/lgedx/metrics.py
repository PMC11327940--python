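"""Diagnostic-accuracy metrics, agreement, and group-comparison statistics.

Point estimates follow the standard 2x2 definitions with ARVC as the
positive class; 95% confidence intervals for proportions use the Wilson
score method.  Group comparisons are the usual contingency-table and
rank-based tests, with per-table Bonferroni thresholds (alpha divided by
the number of tested rows, displayed at 3 decimals).

p-values are delegated to scipy.stats; Cohen's kappa is computed directly
from the agreement table.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .segments import Cohort, Diagnosis

__all__ = [
    "ConfusionTable",
    "DiagnosticMetrics",
    "GroupComparisonResult",
    "TestMethod",
    "confusion_table",
    "diagnostic_metrics",
    "cohen_kappa",
    "compare_binary",
    "compare_continuous",
    "bonferroni_threshold",
    "printed_threshold",
    "round_percent",
]


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 diagnostic counts (positive class = ARVC unless stated otherwise)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_table(
    cohort: Cohort,
    predictions: Mapping[str, bool],
    positive: Diagnosis = Diagnosis.ARVC,
    restrict_to: Optional[Sequence[Diagnosis]] = None,
) -> ConfusionTable:
    """Cross-tabulate binary predictions against the clinical diagnosis.

    ``restrict_to`` limits the evaluated patients to a diagnosis subset,
    e.g. ``[Diagnosis.ARVC, Diagnosis.DCM]`` for the head-to-head ARVC-vs-DCM
    specificity reported per differential.
    """
    patients = list(cohort)
    if restrict_to is not None:
        wanted = set(restrict_to)
        patients = [p for p in patients if p.diagnosis in wanted]
    tp = fp = fn = tn = 0
    for p in patients:
        if p.id not in predictions:
            raise KeyError(f"no prediction for patient id {p.id!r}")
        pred = bool(predictions[p.id])
        truth = p.diagnosis is positive
        if truth and pred:
            tp += 1
        elif truth:
            fn += 1
        elif pred:
            fp += 1
        else:
            tn += 1
    return ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Sensitivity/specificity/accuracy/PPV/NPV with Wilson 95% CIs.

    A metric whose margin is zero (e.g. PPV with no predicted positives) is
    ``None`` rather than 0 — undefined, not wrong.
    """

    sensitivity: Optional[float]
    specificity: Optional[float]
    accuracy: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    ci: dict[str, Optional[tuple[float, float]]]
    table: ConfusionTable

    def as_percent(self) -> dict[str, Optional[int]]:
        """Point estimates rounded half-up to whole percent, as displayed."""
        return {
            name: None if value is None else round_percent(value)
            for name, value in [
                ("sensitivity", self.sensitivity),
                ("specificity", self.specificity),
                ("accuracy", self.accuracy),
                ("ppv", self.ppv),
                ("npv", self.npv),
            ]
        }


def round_percent(proportion: float) -> int:
    """Round a proportion to whole percent, half away from zero (so that
    35/132 displays as 27%, not 26%)."""
    return int(math.floor(proportion * 100 + 0.5))


def _ratio(num: int, den: int, alpha: float) -> tuple[Optional[float], Optional[tuple[float, float]]]:
    if den == 0:
        return None, None
    lo, hi = proportion_confint(num, den, alpha=alpha, method="wilson")
    est = num / den
    # guard against 1-ulp excursions of the score interval at the extremes
    return est, (min(float(lo), est), max(float(hi), est))


def diagnostic_metrics(t: ConfusionTable, alpha: float = 0.05) -> DiagnosticMetrics:
    """Compute the metric set from a 2x2 table.

    sens = tp/(tp+fn), spec = tn/(tn+fp), ppv = tp/(tp+fp),
    npv = tn/(tn+fn), acc = (tp+tn)/n; each with a Wilson score interval.
    """
    sens, ci_sens = _ratio(t.tp, t.tp + t.fn, alpha)
    spec, ci_spec = _ratio(t.tn, t.tn + t.fp, alpha)
    ppv, ci_ppv = _ratio(t.tp, t.tp + t.fp, alpha)
    npv, ci_npv = _ratio(t.tn, t.tn + t.fn, alpha)
    acc, ci_acc = _ratio(t.tp + t.tn, t.n, alpha)
    return DiagnosticMetrics(
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        ppv=ppv,
        npv=npv,
        ci={
            "sensitivity": ci_sens,
            "specificity": ci_spec,
            "accuracy": ci_acc,
            "ppv": ci_ppv,
            "npv": ci_npv,
        },
        table=t,
    )


# ---------------------------------------------------------------------------
# Agreement
# ---------------------------------------------------------------------------

#: Qualitative interpretation bands for kappa (Altman cut-offs: upper bound
#: of each band, inclusive).
KAPPA_BANDS: tuple[tuple[float, str], ...] = (
    (0.20, "poor"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "good"),
    (1.00, "very good"),
)


def kappa_band(kappa: float) -> str:
    for upper, name in KAPPA_BANDS:
        if kappa <= upper:
            return name
    return "very good"


def cohen_kappa(ratings_a: Sequence, ratings_b: Sequence) -> float:
    """Cohen's kappa for two raters over a shared category set.

    kappa = (p_o - p_e) / (1 - p_e), with p_o the observed agreement and
    p_e the chance agreement from the raters' marginal frequencies.  When
    both raters are constant and identical, p_e = 1 and kappa is taken as 1
    by convention (perfect, if degenerate, agreement); a warning is issued.
    """
    if len(ratings_a) != len(ratings_b):
        raise ValueError("rating vectors must have equal length")
    n = len(ratings_a)
    if n == 0:
        raise ValueError("rating vectors must be non-empty")
    categories = sorted(set(ratings_a) | set(ratings_b), key=repr)
    idx = {c: i for i, c in enumerate(categories)}
    k = len(categories)
    table = np.zeros((k, k))
    for a, b in zip(ratings_a, ratings_b):
        table[idx[a], idx[b]] += 1
    table /= n
    p_o = float(np.trace(table))
    p_e = float(table.sum(axis=1) @ table.sum(axis=0))
    if p_e >= 1.0 - 1e-12:
        warnings.warn("both raters constant: kappa defined as 1 by convention")
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

class TestMethod(str, enum.Enum):
    PEARSON_CHI2 = "pearson_chi2"
    YATES_CHI2 = "yates_chi2"
    FISHER_EXACT = "fisher_exact"
    MANN_WHITNEY = "mann_whitney"
    KRUSKAL_WALLIS = "kruskal_wallis"
    AUTO = "auto"


@dataclass(frozen=True)
class GroupComparisonResult:
    test_name: TestMethod
    statistic: float
    p_value: float
    m_comparisons: int = 1
    alpha: float = 0.05

    @property
    def significant_after_bonferroni(self) -> bool:
        return self.p_value < bonferroni_threshold(self.alpha, self.m_comparisons)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-comparison significance level alpha/m."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be a positive integer")
    return alpha / m


def printed_threshold(alpha: float, m: int) -> float:
    """The Bonferroni threshold as displayed in table footnotes: rounded
    half-up to 3 decimals (0.05/12 -> 0.004, 0.05/26 -> 0.002)."""
    raw = bonferroni_threshold(alpha, m)
    return math.floor(raw * 1000 + 0.5) / 1000


def compare_binary(
    k1: int,
    n1: int,
    k2: int,
    n2: int,
    method: TestMethod = TestMethod.AUTO,
    m_comparisons: int = 1,
    alpha: float = 0.05,
) -> GroupComparisonResult:
    """Compare two binomial proportions k1/n1 vs k2/n2 on a 2x2 table.

    ``AUTO`` picks Fisher's exact test when any expected cell count is
    below 5, otherwise the uncorrected Pearson chi-square.  All p-values
    are two-sided.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0 or not 0 <= k <= n:
            raise ValueError("need 0 <= k <= n with n > 0 in each group")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        # degenerate margin: no association testable
        warnings.warn("degenerate 2x2 table; p-value set to 1")
        return GroupComparisonResult(method, math.nan, 1.0, m_comparisons, alpha)
    if method is TestMethod.AUTO:
        expected = stats.contingency.expected_freq(table)
        method = TestMethod.FISHER_EXACT if expected.min() < 5 else TestMethod.PEARSON_CHI2
    if method is TestMethod.FISHER_EXACT:
        res = stats.fisher_exact(table, alternative="two-sided")
        return GroupComparisonResult(method, float(res[0]), float(res[1]), m_comparisons, alpha)
    if method is TestMethod.PEARSON_CHI2:
        res = stats.chi2_contingency(table, correction=False)
    elif method is TestMethod.YATES_CHI2:
        res = stats.chi2_contingency(table, correction=True)
    else:
        raise ValueError(f"method {method} is not a 2x2 test")
    return GroupComparisonResult(method, float(res.statistic), float(res.pvalue), m_comparisons, alpha)


def compare_continuous(
    samples: Sequence[Sequence[float]],
    method: Optional[TestMethod] = None,
    m_comparisons: int = 1,
    alpha: float = 0.05,
) -> GroupComparisonResult:
    """Rank-based comparison of 2+ groups (Mann-Whitney U / Kruskal-Wallis).

    Defaults to Mann-Whitney for two groups and Kruskal-Wallis otherwise;
    ties are handled by mid-ranks (scipy's default).  If every observation
    across all groups is identical the test is vacuous and p = 1.
    """
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group must be non-empty")
    pooled = np.concatenate([np.asarray(s, dtype=float) for s in samples])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical; p-value set to 1")
        name = method or (TestMethod.MANN_WHITNEY if len(samples) == 2 else TestMethod.KRUSKAL_WALLIS)
        return GroupComparisonResult(name, math.nan, 1.0, m_comparisons, alpha)
    if method is None:
        method = TestMethod.MANN_WHITNEY if len(samples) == 2 else TestMethod.KRUSKAL_WALLIS
    if method is TestMethod.MANN_WHITNEY:
        if len(samples) != 2:
            raise ValueError("Mann-Whitney requires exactly two groups")
        res = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
    elif method is TestMethod.KRUSKAL_WALLIS:
        res = stats.kruskal(*samples)
    else:
        raise ValueError(f"method {method} is not a rank test")
    return GroupComparisonResult(method, float(res.statistic), float(res.pvalue), m_comparisons, alpha)


# Per-table comparison counts used for the published Bonferroni footnotes:
# 12 tested rows in the demographics/global-CMR table, 15 in the RV +
# miscellaneous LGE table, 26 in the LV LGE table.
TABLE_COMPARISONS: dict[str, int] = {"table1": 12, "table2": 15, "table3": 26}
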