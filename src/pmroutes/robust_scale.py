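"""Seven estimators of scale, from the classical sample SD to
high-breakdown order-statistic constructions.

All estimators S satisfy the two dispersion-estimate conditions:
shift invariance S(x + c) = S(x) and absolute scale equivariance
S(c*x) = |c| * S(x).

Point estimators
----------------
* ``mean_abs_dev``  — mean absolute deviation about the mean (MADmean).
* ``sample_sd``     — classical SD, divisor n-1.
* ``mad``           — median absolute deviation about the median,
  **unscaled** (no 1.4826 normal-consistency factor); for a normal
  population E[MAD] ~= 0.6745 sigma, roughly (2/3) sigma.
* ``sir``           — semi interquartile range (Q3 - Q1)/2, Tukey hinges.
* ``lms_scale``     — least-median-of-squares scale: half the length of
  the shortest window spanning floor(n/2) order-statistic gaps.

Families
--------
* ``biweight_midvariance`` — Tukey's biweight midvariance with tuning
  constant c; observations further than c MADs from the median get zero
  weight. As c -> inf it tends to the population-style mean square
  deviation about the median.
* ``subrange_scale`` — C_n(alpha): the minimum difference between order
  statistics h = floor(alpha*n)+1 apart, normalised by
  Phi^-1(0.75) - Phi^-1(0.75 - alpha) for normal consistency; as
  alpha -> 0.5 it approaches the LMS construction up to the normaliser.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .descriptives import tukey_hinges
from .series import RouteSeries

__all__ = [
    "ScaleEstimates",
    "mean_abs_dev",
    "sample_sd",
    "mad",
    "sir",
    "biweight_midvariance",
    "biweight_scale",
    "subrange_scale",
    "lms_scale",
    "scale_table",
]


def _values(series) -> np.ndarray:
    if isinstance(series, RouteSeries):
        return series.values
    return np.asarray(series, dtype=float)


def mean_abs_dev(values) -> float:
    """MADmean: (1/n) * sum |x_i - mean|."""
    x = _values(values)
    if x.size < 1:
        raise ValueError("mean_abs_dev requires a non-empty sample")
    return float(np.mean(np.abs(x - x.mean())))


def sample_sd(values) -> float:
    """Classical sample standard deviation, divisor n-1."""
    x = _values(values)
    if x.size < 2:
        raise ValueError("sample_sd requires n >= 2")
    return float(np.std(x, ddof=1))


def mad(values) -> float:
    """Median absolute deviation about the median, unscaled."""
    x = _values(values)
    if x.size < 1:
        raise ValueError("mad requires a non-empty sample")
    return float(np.median(np.abs(x - np.median(x))))


def sir(values) -> float:
    """Semi interquartile range (Q3 - Q1) / 2 with Tukey hinges."""
    q = tukey_hinges(_values(values))
    return (q.q3 - q.q1) / 2.0


def biweight_midvariance(values, c: float = 9.0) -> float:
    """Tukey's biweight midvariance with tuning constant ``c``.

    With M the sample median and D the (unscaled) MAD, set
    u_i = (x_i - M) / (c D) and restrict to A = {i : |u_i| < 1}:

        S_bi^2(c) = n * sum_A (x_i - M)^2 (1 - u_i^2)^4
                    / [ sum_A (1 - u_i^2)(1 - 5 u_i^2) ]^2

    Returns 0 when D = 0 (constant-in-the-middle data have zero robust
    dispersion). Interpretation of c: since E[MAD] ~= (2/3) sigma for
    normal data, c = 9 discards observations more than ~6 SDs out.
    """
    if c <= 0:
        raise ValueError(f"tuning constant c must be > 0, got {c}")
    x = _values(values)
    if x.size < 1:
        raise ValueError("biweight_midvariance requires a non-empty sample")
    m = np.median(x)
    d = float(np.median(np.abs(x - m)))
    if d == 0:
        return 0.0
    u = (x - m) / (c * d)
    keep = np.abs(u) < 1
    xu, uu = x[keep], u[keep]
    num = x.size * np.sum((xu - m) ** 2 * (1 - uu**2) ** 4)
    den = np.sum((1 - uu**2) * (1 - 5 * uu**2)) ** 2
    if den == 0:
        return 0.0
    return float(num / den)


def biweight_scale(values, c: float = 9.0) -> float:
    """Square root of :func:`biweight_midvariance`: a scale in mg/m3."""
    return float(np.sqrt(biweight_midvariance(values, c)))


def subrange_scale(values, alpha: float) -> float:
    """Subrange scale estimator C_n(alpha).

    With h = floor(alpha*n) + 1 and sorted data, the raw statistic is the
    minimum of X(i+h) - X(i) over all start indices i = 1 ... n-h; it is
    divided by Phi^-1(0.75) - Phi^-1(0.75 - alpha) for normal consistency.
    """
    if not 0 < alpha < 0.5:
        raise ValueError(f"alpha must be in (0, 0.5), got {alpha}")
    x = np.sort(_values(values))
    n = x.size
    h = int(np.floor(alpha * n)) + 1
    if n < h + 1:
        raise ValueError(f"n={n} too small for subrange with alpha={alpha}")
    raw = float(np.min(x[h:] - x[:-h]))
    normaliser = stats.norm.ppf(0.75) - stats.norm.ppf(0.75 - alpha)
    return raw / normaliser


def lms_scale(values) -> float:
    """Least-median-of-squares scale: half the shortest difference between
    order statistics floor(n/2) apart."""
    x = np.sort(_values(values))
    n = x.size
    if n < 2:
        raise ValueError("lms_scale requires n >= 2")
    h = n // 2
    return 0.5 * float(np.min(x[h:] - x[:-h]))


@dataclass(frozen=True)
class ScaleEstimates:
    """The five point scale estimates for one route, plus the biweight
    S_bi(c) and subrange C_n(alpha) sweep curves."""

    mad_mean: float
    sd: float
    mad: float
    sir: float
    lms: float
    sbi_c: np.ndarray
    sbi_estimates: np.ndarray
    cn_alphas: np.ndarray
    cn_estimates: np.ndarray


def scale_table(
    series,
    c_grid: np.ndarray | None = None,
    alpha_grid: np.ndarray | None = None,
) -> ScaleEstimates:
    """All seven scale estimators for one route.

    Default sweeps: c = 0.1 ... 18 in steps of 0.1 for S_bi, and
    alpha = 0.005 ... 0.495 in steps of 0.005 for C_n(alpha). Grid points
    where C_n(alpha) is undefined for the sample size are dropped.
    """
    x = _values(series)
    if c_grid is None:
        c_grid = np.round(np.arange(0.1, 18.0 + 1e-9, 0.1), 10)
    if alpha_grid is None:
        alpha_grid = np.round(np.arange(0.005, 0.495 + 1e-9, 0.005), 10)
    sbi = np.array([biweight_scale(x, c) for c in c_grid])
    cn_a, cn_e = [], []
    for a in alpha_grid:
        try:
            cn_e.append(subrange_scale(x, a))
            cn_a.append(a)
        except ValueError:
            continue
    return ScaleEstimates(
        mad_mean=mean_abs_dev(x),
        sd=sample_sd(x) if x.size >= 2 else 0.0,
        mad=mad(x),
        sir=sir(x),
        lms=lms_scale(x) if x.size >= 2 else 0.0,
        sbi_c=np.asarray(c_grid, dtype=float),
        sbi_estimates=sbi,
        cn_alphas=np.asarray(cn_a, dtype=float),
        cn_estimates=np.asarray(cn_e, dtype=float),
    )
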