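"""Rank-based two-sample testing shared by several pipeline stages.

The Wilcoxon rank-sum (Mann–Whitney) test is used for every group-shift
comparison.  For small problems (combined n <= EXACT_LIMIT) the two-sided
p-value is computed by exhaustive enumeration of group assignments on the
observed values, which is exact even under ties; larger problems use the
normal approximation with tie and continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

EXACT_LIMIT = 20


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # Mann-Whitney U of the first sample
    p_value: float
    n_x: int
    n_y: int
    method: str  # "exact" or "asymptotic"


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U = #(x_i > y_j) + 0.5 #(x_i == y_j)."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def rank_sum_test(x, y) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test of two independent samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both groups must be nonempty")
    n, m = x.size, y.size
    u_obs = _u_statistic(x, y)
    mu = n * m / 2.0

    if n + m <= EXACT_LIMIT:
        # U from midranks equals #(x>y) + 0.5 #(x==y); enumerating all
        # C(n+m, n) group assignments of the pooled values gives the exact
        # permutation distribution, valid under ties.
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        combs = np.array(list(combinations(range(n + m), n)))
        u_all = ranks[combs].sum(axis=1) - n * (n + 1) / 2.0
        dev_obs = abs(u_obs - mu)
        p = float(np.mean(np.abs(u_all - mu) >= dev_obs - 1e-12))
        return RankSumResult(u_obs, p, n, m, "exact")

    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return RankSumResult(float(res.statistic), float(res.pvalue), n, m, "asymptotic")


def ecdf(values) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF coordinates (sorted values, cumulative fractions)."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("empty sample")
    return v, np.arange(1, v.size + 1) / v.size
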