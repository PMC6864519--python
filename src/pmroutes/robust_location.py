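"""Robust L-estimators of location: the alpha-trimmed mean family and
the trimean, plus the trimming sweep used to compare them with the
nonparametric median band.

The alpha-trimmed mean discards the ``floor(n*alpha)`` smallest and
largest order statistics and averages the rest; alpha = 0 recovers the
arithmetic mean and, for odd n, the heaviest permitted trimming recovers
the median. The trimean is (Q1 + 2*Q2 + Q3) / 4 with Tukey hinges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .descriptives import tukey_hinges
from .nonparametric import MedianCI
from .series import RouteSeries

__all__ = ["TrimmedCurve", "trimmed_mean", "trimean", "trimmed_curve"]


@dataclass(frozen=True)
class TrimmedCurve:
    """Trimmed-mean sweep for one route, with companion point estimates
    and (optionally) the route's median confidence band for overlay."""

    alphas: np.ndarray
    estimates: np.ndarray
    mean: float
    median: float
    trimean: float
    reference_band: MedianCI | None = None


def _values(series) -> np.ndarray:
    if isinstance(series, RouteSeries):
        return series.values
    return np.asarray(series, dtype=float)


def trimmed_mean(values, alpha: float) -> float:
    """Mean of the order statistics X(g+1) ... X(n-g), g = floor(n*alpha).

    ``alpha`` must lie in [0, 0.5); at least one observation must survive
    the trimming.
    """
    if not 0 <= alpha < 0.5:
        raise ValueError(f"alpha must be in [0, 0.5), got {alpha}")
    x = np.sort(_values(values))
    n = x.size
    if n < 1:
        raise ValueError("trimmed_mean requires a non-empty sample")
    g = int(np.floor(n * alpha))
    if n - 2 * g < 1:
        raise ValueError(f"alpha={alpha} trims away all {n} observations")
    return float(x[g : n - g].mean())


def trimean(values) -> float:
    """Tukey's trimean (Q1 + 2*Q2 + Q3) / 4 using Tukey hinges."""
    q = tukey_hinges(_values(values))
    return (q.q1 + 2.0 * q.q2 + q.q3) / 4.0


def trimmed_curve(
    series,
    n_points: int = 99,
    reference_band: MedianCI | None = None,
) -> TrimmedCurve:
    """Evaluate the trimmed mean over an even alpha-grid in [0, 0.49].

    Low alpha keeps the extreme data; high alpha keeps only the centre of
    the distribution. The curve is a staircase: estimates change only when
    floor(n*alpha) increments.
    """
    x = _values(series)
    alphas = np.linspace(0.0, 0.49, n_points)
    estimates = np.array([trimmed_mean(x, a) for a in alphas])
    return TrimmedCurve(
        alphas=alphas,
        estimates=estimates,
        mean=float(np.mean(x)),
        median=float(np.median(x)),
        trimean=trimean(x),
        reference_band=reference_band,
    )
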