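"""Hypothesis tests and cohort summaries.

Both tests are implemented from first principles (log-factorial
hypergeometric masses, rank enumeration) rather than delegated to a
statistics library, so that every p-value in the pipeline is traceable to
the definitions below.  Fisher's exact test is used for Boolean outcomes
(passed / not passed, ruptured / intact); the Mann-Whitney test for
continuous ones (passage times, speeds).

Two-sided conventions
---------------------
* Fisher: the p-value sums the hypergeometric probabilities of every table
  with the observed margins whose probability does not exceed that of the
  observed table (the "probability <= observed" rule).
* Mann-Whitney: exact combinatorial U distribution (dynamic program over
  rank sums) when the pooled sample is small and tie-free, otherwise a
  normal approximation with tie correction and a 0.5 continuity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["fisher_exact_2x2", "mann_whitney", "summarize", "Summary"]

_REL_TOL = 1.0 + 1e-7  # guards against float noise in the mass comparison


def _log_comb(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def _hypergeom_logpmf(k: int, n: int, K: int, N: int) -> float:
    """log P(X = k) for X ~ Hypergeom(N, K, n)."""
    return _log_comb(K, k) + _log_comb(N - K, n - k) - _log_comb(N, n)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 contingency table.

    Parameters
    ----------
    table : array-like of shape (2, 2)
        Non-negative integer counts ``[[a, b], [c, d]]``.

    Returns
    -------
    float
        Two-sided p-value.  A zero margin carries no evidence and returns 1.
    """
    (a, b), (c, d) = np.asarray(table, dtype=int).tolist()
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    n1 = a + b          # row 1 margin
    k1 = a + c          # column 1 margin
    N = a + b + c + d
    if N == 0 or n1 == 0 or n1 == N or k1 == 0 or k1 == N:
        return 1.0
    lo = max(0, n1 + k1 - N)
    hi = min(n1, k1)
    logp_obs = _hypergeom_logpmf(a, n1, k1, N)
    p_obs = math.exp(logp_obs)
    total = 0.0
    for k in range(lo, hi + 1):
        p_k = math.exp(_hypergeom_logpmf(k, n1, k1, N))
        if p_k <= p_obs * _REL_TOL:
            total += p_k
    if total > 1.0 - 1e-9:      # all tables qualify; sum is 1 up to rounding
        return 1.0
    return total


def _midranks(pooled: np.ndarray) -> np.ndarray:
    """Ranks (1-based) with ties given their average rank."""
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled), dtype=float)
    i = 0
    s = pooled[order]
    while i < len(s):
        j = i
        while j + 1 < len(s) and s[j + 1] == s[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _rank_sum_counts(n: int, m: int) -> np.ndarray:
    """Number of size-``m`` subsets of ranks {1..n} for each possible rank
    sum (index = sum).  Dynamic program over the ranks."""
    max_sum = m * n
    dp = np.zeros((m + 1, max_sum + 1))
    dp[0, 0] = 1.0
    for v in range(1, n + 1):
        for k in range(min(v, m), 0, -1):
            dp[k, v:] += dp[k - 1, :max_sum + 1 - v]
    return dp[m]


def mann_whitney(x, y, *, exact_limit: int = 25,
                 continuity: bool = True) -> tuple[float, float]:
    """Mann-Whitney U test (two-sided).

    Returns ``(U, p)`` where ``U`` is the statistic of the first sample
    (number of ``(x_i, y_j)`` pairs with ``x_i > y_j``, counting ties 0.5).
    Exact via the combinatorial rank-sum distribution when the pooled size
    is at most ``exact_limit`` and no ties are present; otherwise a
    tie-corrected normal approximation with optional continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return nx * ny / 2.0, 1.0
    ranks = _midranks(pooled)
    rx = float(ranks[:nx].sum())
    u = rx - nx * (nx + 1) / 2.0
    mu = nx * ny / 2.0
    has_ties = len(np.unique(pooled)) < pooled.size

    if nx + ny <= exact_limit and not has_ties:
        # the pooled values enter only through their ranks, so the null
        # distribution of U is purely combinatorial
        counts = _rank_sum_counts(nx + ny, nx)
        sums = np.arange(counts.size)
        u_all = sums - nx * (nx + 1) / 2.0
        qualifying = np.abs(u_all - mu) >= abs(u - mu) - 1e-12
        return u, float(counts[qualifying].sum() / counts.sum())

    # Normal approximation with tie correction.
    n = nx + ny
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    var = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return u, 1.0
    dev = abs(u - mu)
    if continuity:
        dev = max(dev - 0.5, 0.0)
    z = dev / math.sqrt(var)
    p = math.erfc(z / math.sqrt(2.0))
    return u, min(p, 1.0)


@dataclass(frozen=True)
class Summary:
    mean: float
    sd: float
    sem: float  # NaN when n == 1
    n: int


def summarize(values) -> Summary:
    """Mean, sample s.d. (n-1 denominator), s.e.m. and n.

    With a single value the s.e.m. is undefined and reported as NaN.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("summarize requires at least one finite value")
    mean = float(v.mean())
    if v.size == 1:
        return Summary(mean=mean, sd=0.0, sem=float("nan"), n=1)
    sd = float(v.std(ddof=1))
    return Summary(mean=mean, sd=sd, sem=sd / math.sqrt(v.size), n=int(v.size))
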