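"""Statistical primitives used throughout the pipeline.

Three primitives carry the whole analysis: a two-sided Wilcoxon rank-sum
test (sex-biased calling and every group comparison), the hypergeometric
upper tail (set over-representation), and Benjamini-Hochberg step-up FDR
(multiple-testing control over enrichment tables).

The rank-sum test switches between an exact null distribution and a normal
approximation.  Several real datasets have tiny groups (down to 1 vs 8
samples), where the normal approximation is unreliable, so for combined
sample sizes up to ``EXACT_CUTOFF`` the permutation distribution of the
rank sum is enumerated exactly (with midranks, so ties are handled
identically in both branches).  Above the cutoff a tie-corrected normal
approximation with continuity correction is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

__all__ = ["RankSumResult", "ranksum", "hypergeom_upper", "bh_fdr", "EXACT_CUTOFF"]

#: Combined-sample-size cutoff below which the exact permutation
#: distribution is enumerated (C(16, 8) = 12870 arrangements at worst).
EXACT_CUTOFF = 16


@dataclass(frozen=True)
class RankSumResult:
    """Outcome of a two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Attributes
    ----------
    u_statistic:
        Mann-Whitney U for the first sample; lies in ``[0, n1 * n2]``.
    p_two_sided:
        Two-sided p-value in ``(0, 1]``, obtained by doubling the smaller
        tail and capping at 1.
    method:
        ``"exact"`` or ``"normal_approx"``.
    """

    u_statistic: float
    p_two_sided: float
    method: str


def _exact_tail_counts(doubled_ranks: np.ndarray, n1: int, w_obs: int) -> tuple[int, int, int]:
    """Count arrangements with rank sum <= / >= the observed one.

    Dynamic program over the multiset of pooled ranks (doubled so midranks
    become integers): ``dp[j, s]`` counts the size-``j`` subsets with
    doubled-rank sum ``s``.  Returns ``(n_le, n_ge, n_total)`` for subsets
    of size ``n1`` relative to ``w_obs``.
    """
    total_sum = int(doubled_ranks.sum())
    # dp indexed [subset size][doubled rank sum]
    dp = np.zeros((n1 + 1, total_sum + 1), dtype=np.float64)
    dp[0, 0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        dp[1:, r:] += dp[:-1, :-r] if r > 0 else dp[:-1, :]
    dist = dp[n1]
    n_total = int(round(dist.sum()))
    n_le = int(round(dist[: w_obs + 1].sum()))
    n_ge = int(round(dist[w_obs:].sum()))
    return n_le, n_ge, n_total


def ranksum(x, y) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test of two independent samples.

    Midranks are assigned to ties.  For ``len(x) + len(y) <=`` the exact
    cutoff, the permutation distribution of the rank sum is enumerated in
    full; otherwise a normal approximation with tie correction and
    continuity correction is applied.  The two-sided p-value doubles the
    smaller tail, capped at 1.

    Raises
    ------
    ValueError
        If either sample is empty or contains non-finite values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("ranksum requires at least one observation per sample")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("ranksum requires finite values; drop NaNs upstream")

    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _sps.rankdata(pooled)  # midranks
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0

    if n1 + n2 <= EXACT_CUTOFF:
        doubled = np.rint(2.0 * ranks).astype(np.int64)
        w_obs = int(round(2.0 * r1))
        n_le, n_ge, n_total = _exact_tail_counts(doubled, n1, w_obs)
        p = min(1.0, 2.0 * min(n_le, n_ge) / n_total)
        return RankSumResult(u_statistic=u1, p_two_sided=p, method="exact")

    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        # every pooled value identical: the test carries no information
        return RankSumResult(u_statistic=u1, p_two_sided=1.0, method="normal_approx")
    z = (abs(u1 - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * _sps.norm.sf(z))
    return RankSumResult(u_statistic=u1, p_two_sided=p, method="normal_approx")


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper tail ``P(X >= k)`` of Hypergeometric(N, K, n).

    ``N`` is the universe size, ``K`` the category size, ``n`` the number
    of draws (query size), and ``k`` the observed overlap.  Evaluated via
    the survival function (log-space internally in scipy) for stability.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    k, K, n, N = int(k), int(K), int(n), int(N)
    if K > N or n > N:
        raise ValueError(f"category size K={K} and draws n={n} must not exceed universe N={N}")
    if k > min(K, n):
        raise ValueError(f"overlap k={k} exceeds min(K={K}, n={n})")
    if k == 0:
        return 1.0
    p = float(_sps.hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 0.0), 1.0)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    Input p-values must lie in ``(0, 1]``.  Returns q-values in the input
    order: ``q(i) = min_{j >= i} p(j) * m / j`` over the sorted sequence,
    clipped at 1, so q-values are monotone non-decreasing in sorted order
    and never smaller than the corresponding p-value.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("bh_fdr expects a non-empty 1-D vector of p-values")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
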