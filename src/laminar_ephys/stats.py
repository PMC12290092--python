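"""Two-group comparison of per-session scalars: Wilcoxon rank-sum and mean+-SEM.

The rank-sum (Mann--Whitney--Wilcoxon) test compares two independent samples
on their ranks.  For small samples the exact null distribution of the
rank-sum W of the first sample is computed over all C(n1+n2, n1) equally
likely assignments of the pooled (mid)ranks, which remains valid with ties;
the two-sided p doubles the smaller tail, capped at 1 -- the standard
convention for discrete exact tests.  Larger samples use the normal
approximation with tie-corrected variance and continuity correction.
"""
from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
from scipy.stats import norm, rankdata


@dataclass
class RankSumResult:
    statistic: float      # rank-sum W of the first sample (midranks)
    p_two_sided: float
    method: str           # "exact" | "normal_approx"
    n1: int
    n2: int


def _exact_tails(doubled_ranks: np.ndarray, n1: int, w2: int
                 ) -> tuple[float, float]:
    """P(W <= w) and P(W >= w) by a shift/DP count over doubled midranks.

    Midranks are multiples of 1/2, so doubling makes them integers; the DP
    counts, for every subset size k and doubled sum s, the number of
    k-subsets of the pooled rank multiset reaching s.  Valid with ties.
    """
    total = int(doubled_ranks.sum())
    dp = np.zeros((n1 + 1, total + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        for k in range(n1, 0, -1):
            dp[k, r:] += dp[k - 1, :total + 1 - r]
    counts = dp[n1]
    n_total = comb(len(doubled_ranks), n1)
    p_le = counts[:w2 + 1].sum() / n_total
    p_ge = counts[w2:].sum() / n_total
    return float(p_le), float(p_ge)


def ranksum_test(x, y, exact_limit: int = 25) -> RankSumResult:
    """Wilcoxon rank-sum test, exact for n1+n2 <= ``exact_limit``.

    Ties receive midranks.  Exact two-sided p = min(1, 2*min(P(W<=w),
    P(W>=w))) under the permutation null of the pooled ranks; otherwise a
    normal approximation with tie-corrected variance and a 0.5 continuity
    correction toward the mean.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w = float(ranks[:n1].sum())
    n = n1 + n2
    if n <= exact_limit:
        doubled = np.round(2.0 * ranks).astype(int)
        w2 = int(round(2.0 * w))
        p_le, p_ge = _exact_tails(doubled, n1, w2)
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return RankSumResult(statistic=w, p_two_sided=p, method="exact",
                             n1=n1, n2=n2)
    mean = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return RankSumResult(statistic=w, p_two_sided=1.0,
                             method="normal_approx", n1=n1, n2=n2)
    diff = w - mean
    cc = 0.5 * np.sign(diff)  # continuity correction toward the mean
    z = (diff - cc) / np.sqrt(var)
    p = min(1.0, 2.0 * norm.sf(abs(z)))
    return RankSumResult(statistic=w, p_two_sided=p, method="normal_approx",
                         n1=n1, n2=n2)


@dataclass
class GroupSummary:
    mean: float
    sem: float  # NaN when n == 1 (SEM undefined)
    n: int


def group_summary(values) -> GroupSummary:
    """Mean and standard error (sample SD with n-1 denominator over sqrt(n))."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("group_summary needs at least one value")
    sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else float("nan")
    return GroupSummary(mean=float(v.mean()), sem=sem, n=int(v.size))
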