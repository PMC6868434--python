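"""Normality-gated two-sample comparison between specificity groups.

Each sample is first checked for normality with the Shapiro-Wilk test; if
both pass (p > alpha), a two-sided two-sample Student's t-test is used,
otherwise the non-parametric two-sided Wilcoxon rank-sum test.  No
multiple-testing correction is applied: comparisons are reported with raw
p-values, one per metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class ComparisonResult:
    metric: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    normality_p_a: float
    normality_p_b: float
    test_used: str  # t_test | wilcoxon_rank_sum
    statistic: float
    p_value: float


def compare_groups(
    values_a,
    values_b,
    alpha_normality: float = 0.05,
    metric: str = "",
    group_a: str = "A",
    group_b: str = "B",
) -> ComparisonResult:
    """Shapiro-Wilk-gated two-sample comparison (two-sided)."""
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each sample needs n >= 3 for the normality gate")
    # Shapiro-Wilk is undefined for zero-variance data; such samples are
    # treated as non-normal (p = 0) so the rank-sum branch is taken
    def _shapiro_p(x: np.ndarray) -> float:
        if np.ptp(x) == 0.0:
            return 0.0
        return float(stats.shapiro(x).pvalue)

    p_a = _shapiro_p(a)
    p_b = _shapiro_p(b)
    if p_a > alpha_normality and p_b > alpha_normality:
        res = stats.ttest_ind(a, b)
        test_used = "t_test"
    else:
        res = stats.ranksums(a, b)
        test_used = "wilcoxon_rank_sum"
    return ComparisonResult(
        metric=metric,
        group_a=group_a,
        group_b=group_b,
        n_a=len(a),
        n_b=len(b),
        normality_p_a=p_a,
        normality_p_b=p_b,
        test_used=test_used,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )


def comparison_record(r: ComparisonResult) -> dict:
    return {
        "metric": r.metric,
        "group_a": r.group_a,
        "group_b": r.group_b,
        "n_a": r.n_a,
        "n_b": r.n_b,
        "normality_p_a": round(r.normality_p_a, 4),
        "normality_p_b": round(r.normality_p_b, 4),
        "test_used": r.test_used,
        "statistic": round(r.statistic, 4),
        "p_value": r.p_value,
    }
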