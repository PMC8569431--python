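"""Shared statistical kernels used across the pipeline stages.

Most tests wrap the standard scipy routines; the exceptions are
written out here because the pipeline needs behaviour those routines do not
provide: an exact Mann-Whitney U with mid-rank ties by full enumeration
(scipy's exact method refuses ties), and a pooled two-sample t whose
variance is pooled across *all* replicate groups measured at a temperature,
not just the two groups being compared (degrees of freedom
``sum(n_i - 1)`` over every group in the pool).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "fisher_exact_2x2",
    "MannWhitneyResult",
    "mann_whitney",
    "bh_fdr",
    "holm_adjust",
    "two_proportion_z",
    "PooledTResult",
    "pooled_group_t",
    "variance_ratio_test",
]

ALTERNATIVES = {"two-sided", "less", "greater"}


def fisher_exact_2x2(table, alternative: str = "two-sided") -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    The two-sided p sums every hypergeometric outcome whose probability does
    not exceed the observed table's.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.number):
        raise ValueError("counts must be non-negative")
    if np.any(arr != np.floor(arr)):
        raise ValueError("counts must be integers")
    return float(sps.fisher_exact(arr.astype(int), alternative=alternative)[1])


@dataclass(frozen=True)
class MannWhitneyResult:
    U: float  # U statistic of the first sample
    p_value: float
    method: str  # "exact" | "asymptotic"
    degenerate: bool = False  # all values tied across both groups


def _rank_sum_tail_probs(ranks: np.ndarray, n1: int, r1: float) -> tuple[float, float]:
    """Exact P(R <= r1) and P(R >= r1) of the first group's rank sum over
    all label assignments, mid-rank ties included.

    Counting by dynamic programming over doubled ranks (mid-ranks are
    half-integers, so doubling makes them exact integers): dp[k][s] is the
    number of k-subsets with doubled rank sum s.  Equivalent to full
    enumeration of the C(n, n1) assignments but polynomial time.
    """
    doubled = np.rint(2.0 * ranks).astype(np.int64)
    if not np.allclose(doubled, 2.0 * ranks):
        raise ValueError("ranks are not half-integers; cannot enumerate exactly")
    smax = int(doubled.sum())
    dp = np.zeros((n1 + 1, smax + 1), dtype=float)
    dp[0, 0] = 1.0
    for d in doubled:
        for k in range(n1, 0, -1):
            dp[k, d:] += dp[k - 1, : smax + 1 - d]
    counts = dp[n1]
    total = counts.sum()
    r1d = 2.0 * r1
    sums = np.arange(smax + 1)
    tol = 1e-9
    p_less = counts[sums <= r1d + tol].sum() / total
    p_greater = counts[sums >= r1d - tol].sum() / total
    return float(p_less), float(p_greater)


def mann_whitney(
    x,
    y,
    alternative: str = "two-sided",
    exact_limit: int = 24,
) -> MannWhitneyResult:
    """Mann-Whitney U test of ``x`` against ``y``.

    Exact p by enumeration of the rank-sum assignment distribution
    (mid-rank ties handled) when the combined sample size is at most
    ``exact_limit`` - the default covers two groups of 12, the
    experiment's design - otherwise the normal approximation with tie and
    continuity corrections.  ``alternative`` "less" means ``x`` tends to
    take smaller values than ``y``.
    """
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {sorted(ALTERNATIVES)}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    n1, n2 = x.size, y.size
    ranks = sps.rankdata(pooled)  # mid-ranks
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0

    if np.all(pooled == pooled[0]):
        return MannWhitneyResult(U=u1, p_value=1.0, method="degenerate", degenerate=True)

    if n1 + n2 <= exact_limit:
        p_less, p_greater = _rank_sum_tail_probs(ranks, n1, r1)
        if alternative == "less":
            p = p_less
        elif alternative == "greater":
            p = p_greater
        else:
            p = min(1.0, 2.0 * min(p_less, p_greater))
        return MannWhitneyResult(U=u1, p_value=float(p), method="exact")

    # normal approximation with tie correction and continuity correction
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sigma = math.sqrt(sigma2)
    if alternative == "less":
        z = (u1 - mu + 0.5) / sigma
        p = sps.norm.cdf(z)
    elif alternative == "greater":
        z = (u1 - mu - 0.5) / sigma
        p = sps.norm.sf(z)
    else:
        z = (u1 - mu - math.copysign(0.5, u1 - mu)) / sigma if u1 != mu else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
    return MannWhitneyResult(U=u1, p_value=float(min(p, 1.0)), method="asymptotic")


def _check_pvalues(pvalues) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    if p.size and np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending order; monotone
    in the input ranking.
    """
    p = _check_pvalues(pvalues)
    m = p.size
    if m == 0:
        return p
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def holm_adjust(pvalues, method: str = "holm") -> np.ndarray:
    """Family-wise error adjusted p-values (Holm step-down or Bonferroni)."""
    p = _check_pvalues(pvalues)
    m = p.size
    if m == 0:
        return p
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    if method != "holm":
        raise ValueError("method must be 'holm' or 'bonferroni'")
    order = np.argsort(p, kind="mergesort")
    stepdown = (m - np.arange(m)) * p[order]
    adj_sorted = np.minimum(np.maximum.accumulate(stepdown), 1.0)
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj


def two_proportion_z(k1: int, n1: int, k2: int, n2: int, alternative: str = "two-sided"):
    """Pooled two-proportion z-test; returns ``(z, p)``.

    z = (p1 - p2) / sqrt(p*(1-p*)(1/n1 + 1/n2)) with p* the pooled
    proportion (k1+k2)/(n1+n2).
    """
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {sorted(ALTERNATIVES)}")
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0 or not (0 <= k <= n):
            raise ValueError("need 0 <= k <= n with n > 0")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return 0.0, 1.0
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    if alternative == "two-sided":
        p = 2.0 * sps.norm.sf(abs(z))
    elif alternative == "greater":
        p = float(sps.norm.sf(z))
    else:
        p = float(sps.norm.cdf(z))
    return float(z), float(min(p, 1.0))


@dataclass(frozen=True)
class PooledTResult:
    t_stat: float
    p_value: float
    df: int
    s_pooled: float
    mean_1: float
    mean_0: float
    n1: int
    n0: int


def pooled_group_t(x1, x0, pool_groups=None) -> PooledTResult:
    """Two-sample t with variance pooled across many replicate groups.

    ``x1`` and ``x0`` are the two groups being compared;
    ``pool_groups`` is the collection of *all* replicate groups whose
    within-group deviations estimate the common variance (it must include
    the compared groups; defaults to just those two, which reduces to the
    classical equal-variance two-sample t-test).

    t = (mean(x1) - mean(x0)) / (s_p * sqrt(1/n1 + 1/n0)),
    s_p^2 = sum_i sum_j (x_ij - mean_i)^2 / sum_i (n_i - 1),
    df = sum_i (n_i - 1).  Two-sided p.
    """
    x1 = np.asarray(x1, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    if x1.size < 2 or x0.size < 2:
        raise ValueError("both compared groups need >= 2 replicates")
    groups = [np.asarray(g, dtype=float) for g in (pool_groups or [x1, x0])]
    ss = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    df = sum(g.size - 1 for g in groups)
    if df <= 0:
        raise ValueError("pooled degrees of freedom must be positive")
    sp2 = ss / df
    if sp2 <= 0:
        raise ValueError("zero pooled variance: the t statistic is undefined")
    sp = math.sqrt(sp2)
    se = sp * math.sqrt(1.0 / x1.size + 1.0 / x0.size)
    t = (x1.mean() - x0.mean()) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return PooledTResult(
        t_stat=float(t),
        p_value=float(p),
        df=int(df),
        s_pooled=sp,
        mean_1=float(x1.mean()),
        mean_0=float(x0.mean()),
        n1=int(x1.size),
        n0=int(x0.size),
    )


def variance_ratio_test(group_a, group_b):
    """Two-sided F test of equality of variances; returns ``(F, p)``.

    F = var(a)/var(b) with (n_a - 1, n_b - 1) degrees of freedom; swapping
    the groups inverts F and leaves p unchanged.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs >= 3 values")
    va = float(np.var(a, ddof=1))
    vb = float(np.var(b, ddof=1))
    if vb == 0:
        raise ValueError("zero variance in denominator group")
    f = va / vb
    dfa, dfb = a.size - 1, b.size - 1
    p = 2.0 * min(sps.f.cdf(f, dfa, dfb), sps.f.sf(f, dfa, dfb))
    return float(f), float(min(p, 1.0))
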