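"""Core container for one route's ordered concentration measurements.

A *route* is a walked transect along which a portable particle monitor
records PM2.5 mass concentration; measurements are time-ordered and
expressed in mg/m3 throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class RouteSeries:
    """One route's ordered, nonnegative PM2.5 concentrations (mg/m3).

    Parameters
    ----------
    route_id
        Route label (e.g. ``"X1"``).
    values
        Time-ordered concentrations in mg/m3; all finite and >= 0.
    timestamps
        Optional ISO-8601 strings, same length as ``values``. Carried
        opaquely; no temporal computation uses them.
    coords
        Optional (lat, lon) pairs in decimal degrees, same length as
        ``values``. Carried opaquely.
    """

    route_id: str
    values: np.ndarray
    timestamps: tuple[str, ...] | None = None
    coords: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise ValueError(f"route {self.route_id!r}: values must be 1-D")
        if vals.size and not np.all(np.isfinite(vals)):
            raise ValueError(f"route {self.route_id!r}: non-finite value")
        if vals.size and vals.min() < 0:
            raise ValueError(f"route {self.route_id!r}: negative concentration")
        object.__setattr__(self, "values", vals)
        for name in ("timestamps", "coords"):
            aux = getattr(self, name)
            if aux is not None and len(aux) != vals.size:
                raise ValueError(
                    f"route {self.route_id!r}: {name} length {len(aux)} "
                    f"!= {vals.size} values"
                )

    @property
    def n(self) -> int:
        return int(self.values.size)

    def __len__(self) -> int:
        return self.n

    def with_values(self, values: np.ndarray) -> "RouteSeries":
        """Copy of this series with ``values`` replaced (metadata dropped
        when lengths no longer match)."""
        values = np.asarray(values, dtype=float)
        keep = values.size == self.n
        return RouteSeries(
            route_id=self.route_id,
            values=values,
            timestamps=self.timestamps if keep else None,
            coords=self.coords if keep else None,
        )
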