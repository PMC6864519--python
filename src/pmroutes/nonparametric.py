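"""Exact nonparametric inference for the median and two-group comparison.

Three tools, all distribution-free:

* **Sign test** for H0: Median = m0 against a two-sided alternative. The
  statistic K counts observations above m0; under H0, after discarding
  ties with m0, K ~ Binomial(h, 1/2) where h is the number of non-ties.

* **Order-statistic confidence interval** for the median. With
  K ~ Binomial(n, 1/2), choose k' as the largest integer with
  P(K <= k') <= alpha/2 and k as the smallest integer with
  P(K >= k) <= alpha/2; the interval [X(k'+1), X(k)] (1-based order
  statistics) then covers the median with probability
  1 - P(K <= k') - P(K >= k) >= 1 - alpha.

* **Wilcoxon rank-sum test** with midranks for ties, the tie-corrected
  variance, continuity correction, and a one-sided upper-tail normal
  p-value (alternative: the designated sample is stochastically larger).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .series import RouteSeries

__all__ = [
    "SignTestResult",
    "MedianCI",
    "RankSumResult",
    "sign_test",
    "median_ci",
    "ranksum_test",
    "SampleTooSmallError",
]


class SampleTooSmallError(ValueError):
    """No two-sided order-statistic interval exists at the requested level."""


@dataclass(frozen=True)
class SignTestResult:
    m0: float
    k: int  # observations strictly above m0
    h: int  # effective sample size after discarding ties
    p_value: float


@dataclass(frozen=True)
class MedianCI:
    """Exact order-statistic interval for the median.

    ``lower_index``/``upper_index`` are 1-based order-statistic indices;
    ``coverage`` is the achieved (conservative) confidence level.
    """

    alpha: float
    lower_index: int
    upper_index: int
    lower: float
    upper: float
    coverage: float

    @property
    def length(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class RankSumResult:
    w: float          # rank-sum of the designated (Y) sample, midranks
    expected: float   # n_y (N+1) / 2
    variance: float   # tie-corrected var(W)
    z: float          # continuity-corrected standardized statistic
    p_value: float    # one-sided upper-tail normal probability


def _values(series) -> np.ndarray:
    if isinstance(series, RouteSeries):
        return series.values
    return np.asarray(series, dtype=float)


def sign_test(series, m0: float) -> SignTestResult:
    """Two-sided sign test of H0: Median = ``m0``.

    Ties with ``m0`` are discarded; with k observations above m0 among h
    non-ties, p = min(1, 2 * min(P(K<=k), P(K>=k))), K ~ Binomial(h, 1/2).
    """
    x = _values(series)
    above = int(np.sum(x > m0))
    below = int(np.sum(x < m0))
    h = above + below
    if h == 0:
        raise ValueError("sign test degenerate: every observation equals m0")
    k = above
    lower_tail = float(stats.binom.cdf(k, h, 0.5))
    upper_tail = float(stats.binom.sf(k - 1, h, 0.5))
    p = min(1.0, 2.0 * min(lower_tail, upper_tail))
    return SignTestResult(m0=float(m0), k=k, h=h, p_value=p)


def median_ci(series, alpha: float = 0.05) -> MedianCI:
    """Exact two-sided order-statistic confidence interval for the median.

    Raises :class:`SampleTooSmallError` when even the extreme order
    statistics cannot achieve the level (e.g. n = 5 at alpha = 0.05, where
    the smallest tail probability 1/32 already exceeds alpha/2).
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    x = np.sort(_values(series))
    n = x.size
    if n < 1:
        raise ValueError("median_ci requires a non-empty sample")
    half = alpha / 2.0
    # largest k' with P(K <= k') <= alpha/2; P(K <= -1) = 0 never qualifies
    # beyond k' = -1, which leaves no lower order statistic.
    if stats.binom.cdf(0, n, 0.5) > half:
        raise SampleTooSmallError(
            f"n={n} too small for a two-sided level-{alpha} interval: "
            f"P(K<=0) = {stats.binom.cdf(0, n, 0.5):.4g} > {half:.4g}"
        )
    k_prime = int(stats.binom.ppf(half, n, 0.5))
    if stats.binom.cdf(k_prime, n, 0.5) > half:  # ppf rounds up; step back
        k_prime -= 1
    # smallest k with P(K >= k) <= alpha/2; by symmetry k = n - k'
    k = n - k_prime
    lower_tail = float(stats.binom.cdf(k_prime, n, 0.5))
    upper_tail = float(stats.binom.sf(k - 1, n, 0.5))
    coverage = 1.0 - lower_tail - upper_tail
    lower_index = k_prime + 1
    upper_index = k
    if not lower_index < upper_index:
        raise SampleTooSmallError(
            f"n={n}: interval indices collapse at level {alpha}"
        )
    return MedianCI(
        alpha=float(alpha),
        lower_index=lower_index,
        upper_index=upper_index,
        lower=float(x[lower_index - 1]),
        upper=float(x[upper_index - 1]),
        coverage=coverage,
    )


def ranksum_test(y_sample, x_sample) -> RankSumResult:
    """One-sided Wilcoxon rank-sum test (alternative: Y stochastically
    larger than X) with midranks, tie-corrected variance and continuity
    correction.

    With pooled size N = n_x + n_y and tie groups of sizes t_j:

        E(W)   = n_y (N+1) / 2
        var(W) = (n_x n_y / 12) [ (N+1) - sum_j (t_j^3 - t_j) / (N(N-1)) ]
        z      = (W - E(W) - 1/2) / sqrt(var(W)),  p = P(Z >= z)
    """
    y = _values(y_sample)
    x = _values(x_sample)
    if y.size == 0 or x.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([y, x])
    n_y, n_x = y.size, x.size
    big_n = n_y + n_x
    ranks = stats.rankdata(pooled, method="average")
    w = float(ranks[:n_y].sum())
    expected = n_y * (big_n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    variance = (n_x * n_y / 12.0) * (
        (big_n + 1) - tie_term / (big_n * (big_n - 1))
    )
    if variance <= 0:
        raise ValueError("rank-sum degenerate: zero variance (all values tied)")
    z = (w - expected - 0.5) / np.sqrt(variance)
    p = float(stats.norm.sf(z))
    return RankSumResult(
        w=w, expected=expected, variance=float(variance), z=float(z), p_value=p
    )
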