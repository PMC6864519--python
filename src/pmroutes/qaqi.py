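"""Air-quality-index band classification and grouped comparison.

The default band system is the Quito Air Quality Index (QAQI) for 24-h
PM2.5 concentration, six contiguous half-open bands in mg/m3:
Desirable [0, 0.025), Acceptable [0.025, 0.050), Caution [0.050, 0.150),
Alert [0.150, 0.250), Alarm [0.250, 0.350), Emergency [0.350, inf).

A route is classified from its nonparametric median confidence interval.
Two views are exposed, because an interval can straddle a band boundary:

* the **candidate set** — every band the interval intersects;
* a single **conservative label** — the band containing the interval's
  upper endpoint (the worst level the median cannot be excluded from).

The grouped comparison encodes each route by its band's ordinal index and
runs the one-sided tie-corrected rank-sum test with the designated group
as the stochastically-larger alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import math

import pandas as pd

from .nonparametric import MedianCI, RankSumResult, ranksum_test

__all__ = [
    "Band",
    "BandSystem",
    "QAQI_BANDS",
    "classify_value",
    "classify_route",
    "contingency",
    "compare_groups",
]


@dataclass(frozen=True)
class Band:
    name: str
    lower: float  # inclusive
    upper: float  # exclusive

    def contains(self, x: float) -> bool:
        return self.lower <= x < self.upper


@dataclass(frozen=True)
class BandSystem:
    """Ordered, contiguous, half-open bands covering [0, inf)."""

    bands: tuple[Band, ...]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("band system must contain at least one band")
        if self.bands[0].lower != 0:
            raise ValueError("first band must start at 0")
        if not math.isinf(self.bands[-1].upper):
            raise ValueError("last band must extend to infinity")
        for a, b in zip(self.bands, self.bands[1:]):
            if a.upper != b.lower:
                raise ValueError(f"bands {a.name!r} and {b.name!r} not contiguous")
            if a.upper <= a.lower:
                raise ValueError(f"band {a.name!r} is empty")

    @classmethod
    def from_limits(cls, spec: Sequence[tuple[str, float, float]]) -> "BandSystem":
        return cls(tuple(Band(n, lo, hi) for n, lo, hi in spec))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.bands)

    def ordinal(self, name: str) -> int:
        return self.names.index(name)


QAQI_BANDS = BandSystem.from_limits(
    [
        ("Desirable", 0.0, 0.025),
        ("Acceptable", 0.025, 0.050),
        ("Caution", 0.050, 0.150),
        ("Alert", 0.150, 0.250),
        ("Alarm", 0.250, 0.350),
        ("Emergency", 0.350, math.inf),
    ]
)


def classify_value(x: float, bands: BandSystem = QAQI_BANDS) -> str:
    """Name of the unique half-open band containing ``x`` (mg/m3)."""
    if x < 0:
        raise ValueError(f"concentration must be >= 0, got {x}")
    for band in bands.bands:
        if band.contains(x):
            return band.name
    raise AssertionError("bands do not cover [0, inf)")  # unreachable


def classify_route(
    ci: MedianCI, bands: BandSystem = QAQI_BANDS
) -> tuple[tuple[str, ...], str]:
    """Candidate band set and conservative single label for a median CI.

    Candidates are all bands whose half-open interval intersects the
    closed interval [ci.lower, ci.upper]; the single label is the band of
    the upper endpoint, and always belongs to the candidate set.
    """
    candidates = tuple(
        b.name
        for b in bands.bands
        if b.lower <= ci.upper and ci.lower < b.upper
    )
    label = classify_value(ci.upper, bands)
    return candidates, label


def contingency(
    labels: Mapping[str, str],
    groups: Mapping[str, str],
    bands: BandSystem = QAQI_BANDS,
) -> pd.DataFrame:
    """Group x band count table restricted to bands that occur, with
    Total row and column; band columns keep the band order."""
    missing = set(labels) ^ set(groups)
    if missing:
        raise ValueError(f"routes not both labeled and grouped: {sorted(missing)}")
    if not labels:
        return pd.DataFrame()
    present = [b for b in bands.names if b in set(labels.values())]
    group_names = sorted(set(groups.values()))
    table = pd.DataFrame(0, index=group_names, columns=present, dtype=int)
    for route, band in labels.items():
        table.loc[groups[route], band] += 1
    table["Total"] = table.sum(axis=1)
    table.loc["Total"] = table.sum(axis=0)
    return table


def compare_groups(
    labels: Mapping[str, str],
    groups: Mapping[str, str],
    bands: BandSystem = QAQI_BANDS,
    designated_group: str = "Y",
) -> RankSumResult:
    """One-sided rank-sum comparison of band ordinals between two groups.

    Tests the alternative that pollution in ``designated_group`` is
    stochastically larger than in the other group.
    """
    y_vals = [
        bands.ordinal(labels[r]) for r in labels if groups[r] == designated_group
    ]
    x_vals = [
        bands.ordinal(labels[r]) for r in labels if groups[r] != designated_group
    ]
    return ranksum_test(y_vals, x_vals)
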