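"""Two-sample tests shared by the looping and ATPase comparisons.

Wilcoxon rank-sum for per-experiment looped fractions (exact enumeration
at small n, tie-corrected normal approximation otherwise) and Welch's
unequal-variance t-test for rate comparisons.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy import stats

__all__ = ["rank_sum_test", "welch_t_test", "EXACT_RANKSUM_MAX_N"]

#: combined sample size up to which the rank-sum null is enumerated exactly
EXACT_RANKSUM_MAX_N = 10


def _rank_sum_statistic(pooled_ranks: np.ndarray, idx) -> float:
    return float(pooled_ranks[list(idx)].sum())


def rank_sum_test(x, y):
    """Two-sided Wilcoxon rank-sum test.

    Returns ``(W, p)`` where ``W`` is the rank sum of the first sample
    (mid-ranks on ties).  For combined n <= 10 the p-value is computed by
    full enumeration of all C(n, n1) group assignments (valid with ties);
    otherwise the tie-corrected normal approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w_obs = float(ranks[: x.size].sum())
    n, n1 = pooled.size, x.size

    if n <= EXACT_RANKSUM_MAX_N:
        total = comb(n, n1)
        le = ge = 0
        for idx in combinations(range(n), n1):
            w = _rank_sum_statistic(ranks, idx)
            if w <= w_obs + 1e-9:
                le += 1
            if w >= w_obs - 1e-9:
                ge += 1
        p = min(1.0, 2.0 * min(le, ge) / total)
    else:
        _, p = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        p = float(p)
    return w_obs, p


def welch_t_test(x, y):
    """Welch's unpaired two-tailed t-test with Welch-Satterthwaite df.

    Returns ``(t, p)``.  Each group needs n >= 2.  If both groups have
    zero variance the statistic is undefined; this raises rather than
    silently inflating the variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("Welch's t-test needs n >= 2 per group")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        if np.isclose(x.mean(), y.mean()):
            return 0.0, 1.0
        raise ValueError(
            "both groups have zero variance with different means; "
            "the t statistic is undefined (no epsilon inflation applied)"
        )
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)
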