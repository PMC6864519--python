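"""Synthetic route generator emulating mobile PM2.5 measurement series.

Real route measurements of PM2.5 are nonnegative, strongly right-skewed
and leptokurtic, with occasional extreme spikes (traffic plumes, dust
resuspension) and slow piecewise trends along the walk. The generator
reproduces that structure from four ingredients:

* a **lognormal body**, parameterised by its median (``target_median``)
  and the standard deviation of the log (``body_scale``, so the
  multiplicative spread is ``exp(body_scale)``);
* additive piecewise **trend segments** (start fraction, end fraction,
  offset in mg/m3), clipped at zero — a negative segment clipped at 0
  produces low-side near-zero stretches;
* multiplicative **spike contamination**: a Bernoulli(rate) subset of
  observations is multiplied by ``contamination_scale`` >= 1, mimicking
  the observation that extreme values in this kind of data are high
  values;
* a **seed**, making every series bit-reproducible.

The bundled six-route preset mirrors the published shape of the
motivating campaign: the printed per-route sample sizes and medians, with
spread, trend and contamination chosen to span the Desirable, Acceptable
and Caution air-quality bands.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import datasets
from .series import RouteSeries

__all__ = [
    "RouteSpec",
    "StudySpec",
    "gen_route",
    "gen_study",
    "six_route_preset",
    "derive_route_seed",
]


@dataclass(frozen=True)
class RouteSpec:
    """Parameters for one synthetic route."""

    route_id: str
    n: int
    target_median: float
    body_scale: float = 0.5
    contamination_rate: float = 0.0
    contamination_scale: float = 1.0
    trend_segments: tuple[tuple[float, float, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if self.target_median < 0:
            raise ValueError(f"target_median must be >= 0, got {self.target_median}")
        if self.body_scale < 0:
            raise ValueError(f"body_scale must be >= 0, got {self.body_scale}")
        if not 0 <= self.contamination_rate <= 0.2:
            raise ValueError(
                f"contamination_rate must be in [0, 0.2], got {self.contamination_rate}"
            )
        if self.contamination_scale < 1:
            raise ValueError(
                f"contamination_scale must be >= 1, got {self.contamination_scale}"
            )


@dataclass(frozen=True)
class StudySpec:
    """A collection of routes split into two groups, with a study seed
    from which per-route seeds are derived."""

    routes: tuple[RouteSpec, ...]
    group_of: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [r.route_id for r in self.routes]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate route ids: {ids}")
        missing = [i for i in ids if i not in self.group_of]
        if missing:
            raise ValueError(f"routes without a group: {missing}")


def derive_route_seed(study_seed: int, route_id: str) -> int:
    """Deterministic per-route seed: SHA-256 hash of (study seed, id),
    reduced below 2**31 so routes are independent and reproducible."""
    digest = hashlib.sha256(f"{study_seed}:{route_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def gen_route(spec: RouteSpec) -> RouteSeries:
    """Generate one route series; deterministic in ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal(spec.n)
    if spec.target_median > 0:
        values = spec.target_median * np.exp(spec.body_scale * z)
    else:
        values = np.zeros(spec.n)
    for start, end, offset in spec.trend_segments:
        lo = int(np.floor(start * spec.n))
        hi = int(np.floor(end * spec.n))
        values[lo:hi] += offset
    values = np.clip(values, 0.0, None)
    # the uniform draw happens at every rate so that raising the rate
    # perturbs only the contaminated subset, not the body
    spike = rng.random(spec.n) < spec.contamination_rate
    values = np.where(spike, values * spec.contamination_scale, values)
    return RouteSeries(route_id=spec.route_id, values=values)


def gen_study(spec: StudySpec) -> list[RouteSeries]:
    """One series per route, each seeded from the study seed."""
    out = []
    for route in spec.routes:
        seeded = RouteSpec(
            route_id=route.route_id,
            n=route.n,
            target_median=route.target_median,
            body_scale=route.body_scale,
            contamination_rate=route.contamination_rate,
            contamination_scale=route.contamination_scale,
            trend_segments=route.trend_segments,
            seed=derive_route_seed(spec.seed, route.route_id),
        )
        out.append(gen_route(seeded))
    return out


#: per-route (body_scale, contamination_rate, contamination_scale, trend)
#: for the six-route preset; spread and spikes chosen to mimic the
#: published heavy-tailed shape of each route
_PRESET_SHAPE: dict[str, tuple[float, float, float, tuple]] = {
    "X1": (0.45, 0.05, 10.0, ((0.60, 0.68, -0.034),)),
    "X2": (0.14, 0.0, 1.0, ()),
    "X3": (0.70, 0.0, 1.0, ((0.05, 0.15, -0.010),)),
    "Y1": (0.90, 0.05, 5.0, ()),
    "Y2": (0.50, 0.0, 1.0, ()),
    "Y3": (0.60, 0.05, 5.0, ()),
}


def six_route_preset(seed: int = 0) -> StudySpec:
    """Six-route study shaped like the motivating campaign: published
    sample sizes and target medians, groups X (parallel to the park) and
    Y (perpendicular)."""
    routes = tuple(
        RouteSpec(
            route_id=rid,
            n=datasets.ROUTE_COUNTS[rid],
            target_median=datasets.ROUTE_MEDIANS[rid],
            body_scale=_PRESET_SHAPE[rid][0],
            contamination_rate=_PRESET_SHAPE[rid][1],
            contamination_scale=_PRESET_SHAPE[rid][2],
            trend_segments=_PRESET_SHAPE[rid][3],
        )
        for rid in datasets.ROUTE_IDS
    )
    return StudySpec(routes=routes, group_of=dict(datasets.GROUP_OF), seed=seed)
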