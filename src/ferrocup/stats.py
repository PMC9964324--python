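"""Shared statistical primitives behind the pipeline's significance calls.

Two-group comparisons use the two-sided Wilcoxon rank-sum test: an exact
enumeration when the combined sample size is at most 12 and the data are
tie-free, otherwise a tie-corrected normal approximation with continuity
correction. The omnibus multi-group test is Kruskal-Wallis with tie
correction. Multiple testing uses Benjamini-Hochberg step-up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "wilcoxon_rank_sum",
    "kruskal_wallis",
    "pearson_test",
    "bh_adjust",
    "significance_code",
]

EXACT_N_MAX = 12  # combined-sample cutoff for the exact rank-sum path
_P_FLOOR = float(np.finfo(float).tiny)  # keep p in (0, 1]

#: significance-star thresholds used in group-comparison outputs
SIGNIFICANCE_LEVELS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    method: str
    exact: bool = False
    degenerate: bool = False


def _clamp_p(p: float) -> float:
    return float(min(1.0, max(_P_FLOOR, p)))


def significance_code(p: float) -> str:
    for threshold, code in SIGNIFICANCE_LEVELS:
        if p < threshold:
            return code
    return "ns"


def wilcoxon_rank_sum(a, b) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null enumeration when ``len(a)+len(b) <= 12`` with no ties across
    the pooled data; otherwise normal approximation with tie correction and
    continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("rank-sum test requires non-empty groups")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    use_exact = tie_free and pooled.size <= EXACT_N_MAX
    method = "exact" if use_exact else "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return TestResult(
        statistic=float(res.statistic),
        p=_clamp_p(float(res.pvalue)),
        method=f"wilcoxon_rank_sum_{method}",
        exact=use_exact,
    )


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H with tie correction; chi-square(k-1) reference.

    All-identical pooled data yields H=0, p=1 by convention.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("Kruskal-Wallis requires >=2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.unique(pooled).size == 1:
        return TestResult(0.0, 1.0, "kruskal_wallis", degenerate=True)
    h, p = sps.kruskal(*groups)
    return TestResult(float(h), _clamp_p(float(p)), "kruskal_wallis")


def pearson_test(x, y) -> TestResult:
    """Pearson correlation with two-sided p from t with n-2 df.

    Constant inputs are degenerate: reported as r=0, p=1 with a flag rather
    than an error, so trait-correlation matrices stay rectangular.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson_test requires equal-length vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestResult(0.0, 1.0, "pearson", degenerate=True)
    r, p = sps.pearsonr(x, y)
    return TestResult(float(r), _clamp_p(float(p)), "pearson")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, capped at 1, input order kept."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
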