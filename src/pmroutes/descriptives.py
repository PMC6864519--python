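"""Descriptive statistics for route series.

Summary moments, Tukey-hinge quartiles, centred moving-average smoothing,
box-plot statistics and the notch-style empirical median interval.

Conventions
-----------
* Kurtosis is **non-excess** (a normal sample tends to 3), computed from
  population central moments without small-sample bias correction, as is
  skewness.
* Quartiles are **Tukey hinges** everywhere in this package: the lower /
  upper hinge is the median of the lower / upper half of the sorted data,
  each half including the overall median element when n is odd.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .series import RouteSeries

__all__ = [
    "SummaryStats",
    "Quartiles",
    "summary_stats",
    "tukey_hinges",
    "moving_average",
    "boxplot_stats",
    "empirical_median_ci",
    "relative_error_percent",
]


@dataclass(frozen=True)
class SummaryStats:
    """One summary-table row. ``skewness``/``kurtosis`` are ``None`` when
    the sample variance is zero (shape undefined)."""

    count: int
    mean: float
    median: float
    sd: float
    skewness: float | None
    kurtosis: float | None
    minimum: float
    maximum: float


@dataclass(frozen=True)
class Quartiles:
    q1: float
    q2: float
    q3: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def _values(series) -> np.ndarray:
    if isinstance(series, RouteSeries):
        return series.values
    return np.asarray(series, dtype=float)


def summary_stats(series) -> SummaryStats:
    """Count, mean, median, SD (divisor n-1), min, max, skewness m3/m2^1.5
    and non-excess kurtosis m4/m2^2 for one series."""
    x = _values(series)
    if x.size < 1:
        raise ValueError("summary_stats requires at least one observation")
    n = x.size
    sd = float(np.std(x, ddof=1)) if n >= 2 else 0.0
    if n >= 2 and np.var(x) > 0:
        skew = float(stats.skew(x, bias=True))
        kurt = float(stats.kurtosis(x, fisher=False, bias=True))
    else:
        skew = None
        kurt = None
    return SummaryStats(
        count=n,
        mean=float(np.mean(x)),
        median=float(np.median(x)),
        sd=sd,
        skewness=skew,
        kurtosis=kurt,
        minimum=float(x.min()),
        maximum=float(x.max()),
    )


def tukey_hinges(values) -> Quartiles:
    """Tukey hinges (q1, median, q3).

    Each half includes the overall median element when n is odd:
    ``[1,2,3,4,5] -> (2, 3, 4)``; ``[1,2,3,4] -> (1.5, 2.5, 3.5)``.
    """
    x = np.sort(_values(values))
    n = x.size
    if n == 0:
        raise ValueError("tukey_hinges requires a non-empty sample")
    q2 = float(np.median(x))
    half = (n + 1) // 2  # lower half includes median element for odd n
    q1 = float(np.median(x[:half]))
    q3 = float(np.median(x[n - half :]))
    return Quartiles(q1=q1, q2=q2, q3=q3)


def moving_average(series: RouteSeries, window: int) -> RouteSeries:
    """Centred moving average of nominal size ``window``; the output has
    the same length as the input ("the ends are maintained").

    The window around index i spans ``[i - window//2, i + (window-1)//2]``
    clipped to the series; each output value is the mean of the in-range
    part, so boundary values average over a shorter window.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    x = _values(series)
    n = x.size
    left = window // 2
    right = (window - 1) // 2
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - left)
        hi = min(n, i + right + 1)
        out[i] = x[lo:hi].mean()
    if isinstance(series, RouteSeries):
        return series.with_values(out)
    return out


@dataclass(frozen=True)
class BoxplotStats:
    quartiles: Quartiles
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray


def boxplot_stats(series) -> BoxplotStats:
    """Tukey box-plot statistics: whiskers at the most extreme data points
    inside the 1.5*IQR fences; points outside are outliers."""
    x = _values(series)
    if x.size == 0:
        raise ValueError("boxplot_stats requires a non-empty sample")
    q = tukey_hinges(x)
    lo_fence = q.q1 - 1.5 * q.iqr
    hi_fence = q.q3 + 1.5 * q.iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    outliers = np.sort(x[(x < lo_fence) | (x > hi_fence)])
    return BoxplotStats(
        quartiles=q,
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=outliers,
    )


def empirical_median_ci(series, level: float = 0.95) -> tuple[float, float]:
    """Notch-style empirical interval for the median.

    McGill's notch construction: ``median +/- 1.57 * IQR / sqrt(n)`` with
    the IQR from Tukey hinges. The 1.57 factor targets ~95% pairwise
    comparison of medians; other levels scale the half-width by the
    normal-quantile ratio.
    """
    x = _values(series)
    if x.size == 0:
        raise ValueError("empirical_median_ci requires a non-empty sample")
    q = tukey_hinges(x)
    factor = 1.57
    if level != 0.95:
        factor = 1.57 * stats.norm.ppf(0.5 + level / 2) / stats.norm.ppf(0.975)
    half = factor * q.iqr / np.sqrt(x.size)
    return (q.q2 - half, q.q2 + half)


def relative_error_percent(applied: float, indicated: float) -> int:
    """Relative indication error of a calibration check, rounded to the
    nearest integer percent: ``round(100 * (indicated - applied) / applied)``.
    """
    if applied == 0:
        raise ValueError("applied concentration must be nonzero")
    return int(round(100.0 * (indicated - applied) / applied))
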