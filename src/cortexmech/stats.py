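"""Group-comparison statistics used throughout the study design.

Per-cell mechanical and imaging readouts are compared between
conditions with a two-tailed Mann–Whitney U test (the rank-sum test
Matlab's ``ranksum`` performs): exact by full enumeration of rank
assignments for small samples (combined n ≤ 20, midrank handling of
ties), tie-corrected normal approximation with continuity correction
otherwise.  Blot-style relative changes are tested against 1 with a
one-sided one-sample t-test.  No multiple-testing correction is
applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.stats import rankdata

__all__ = [
    "GroupComparison",
    "mann_whitney",
    "relative_change_test",
    "significance_tier",
    "five_number_summary",
]

EXACT_MAX_N = 20  # combined sample size at which enumeration switches off


def significance_tier(p: float) -> str:
    """Boxplot annotation tier: ns / * / ** / *** at 0.05 / 0.01 / 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def five_number_summary(values) -> dict[str, float]:
    """Median, quartiles and 1.5·IQR whiskers (most extreme data inside)."""
    v = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
    }


@dataclass(frozen=True)
class GroupComparison:
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    U: float
    p: float
    method: str  # "exact" | "asymptotic"
    tier: str
    summary_a: dict
    summary_b: dict


def _exact_ranksum_p(ranks: np.ndarray, n_a: int, rank_sum_a: float) -> float:
    """Two-tailed exact p by enumerating all C(n, n_a) rank assignments.

    Counts subsets of the pooled (midrank) ranks via dynamic
    programming on the doubled ranks (integers even with .5 midranks):
    ``ways[k][s]`` = number of size-k subsets with doubled-rank sum s.
    """
    doubled = np.rint(2.0 * ranks).astype(int)
    total = int(doubled.sum())
    ways = np.zeros((n_a + 1, total + 1), dtype=float)
    ways[0, 0] = 1.0
    for d in doubled:
        for k in range(n_a, 0, -1):
            ways[k, d:] += ways[k - 1, : total + 1 - d]
    dist = ways[n_a]
    n_total = dist.sum()
    obs = int(round(2.0 * rank_sum_a))
    p_low = dist[: obs + 1].sum() / n_total
    p_high = dist[obs:].sum() / n_total
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def mann_whitney(a, b, label_a: str = "a", label_b: str = "b") -> GroupComparison:
    """Two-tailed Mann–Whitney U test with midrank tie handling.

    Exact enumeration for combined n ≤ 20; otherwise the tie-corrected
    normal approximation with continuity correction.  Identical values
    in both groups degenerate to p = 1 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = len(a), len(b)
    if min(n_a, n_b) < 3:
        raise ValueError("each group needs n >= 3")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    rank_sum_a = float(ranks[:n_a].sum())
    U = rank_sum_a - n_a * (n_a + 1) / 2.0

    summary_a = five_number_summary(a)
    summary_b = five_number_summary(b)
    if np.ptp(pooled) == 0:
        warnings.warn("degenerate test: all values identical across both groups")
        return GroupComparison(label_a, label_b, n_a, n_b, U, 1.0, "degenerate",
                               "ns", summary_a, summary_b)

    n = n_a + n_b
    if n <= EXACT_MAX_N:
        p = _exact_ranksum_p(ranks, n_a, rank_sum_a)
        method = "exact"
    else:
        mean_U = n_a * n_b / 2.0
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1))
        var_U = n_a * n_b / 12.0 * ((n + 1) - tie_term)
        if var_U <= 0:
            p = 1.0
        else:
            z = (U - mean_U - 0.5 * np.sign(U - mean_U)) / np.sqrt(var_U)
            p = float(2.0 * sps.norm.sf(abs(z)))
        method = "asymptotic"
    p = min(p, 1.0)
    return GroupComparison(label_a, label_b, n_a, n_b, U, p, method,
                           significance_tier(p), summary_a, summary_b)


def relative_change_test(ratios, direction: str = "greater") -> float:
    """One-sample t-test of relative changes against 1, one-sided.

    ``direction='greater'`` tests whether the mean ratio exceeds 1,
    ``'less'`` whether it falls below 1.
    """
    v = np.asarray(ratios, dtype=float)
    if len(v) < 3:
        raise ValueError("need n >= 3 ratios")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    if np.ptp(v) == 0:
        warnings.warn("degenerate test: zero variance in ratios")
        if v[0] == 1.0:
            return 0.5
        exceeds = v[0] > 1.0
        return 0.0 if exceeds == (direction == "greater") else 1.0
    res = sps.ttest_1samp(v, popmean=1.0, alternative=direction)
    return float(res.pvalue)
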