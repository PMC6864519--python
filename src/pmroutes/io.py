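"""Reading and writing route measurement files and analysis reports.

Routes CSV dialect: header ``route_id,seq,value[,timestamp,lat,lon]``
with ``seq`` 1-based and strictly increasing per route and ``value`` a
nonnegative concentration. The canonical internal unit is mg/m3 (the
air-quality bands are stated in mg/m3); files recorded in ug/m3 are
converted on read by an exact factor of 1000.

The analysis report is a JSON document with one object per table
(summary statistics, median confidence intervals, scale estimates,
classification/contingency, group comparison) plus a CSV export per
per-route table.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .series import RouteSeries

__all__ = [
    "read_routes_csv",
    "write_routes_csv",
    "write_report",
    "read_report",
    "RoutesFormatError",
]

REQUIRED_COLUMNS = ("route_id", "seq", "value")
_UNIT_DIVISOR = {"mg_m3": 1.0, "ug_m3": 1000.0}


class RoutesFormatError(ValueError):
    """Malformed routes CSV (missing columns, bad seq, bad values)."""


def read_routes_csv(path, unit: str = "mg_m3") -> list[RouteSeries]:
    """Parse a routes CSV into one :class:`RouteSeries` per route id.

    Rows are ordered by ``seq`` within each route; values are converted
    to mg/m3 (divide by 1000 when ``unit="ug_m3"``). Negative or
    non-numeric values raise a validation error naming the offending row.
    """
    if unit not in _UNIT_DIVISOR:
        raise ValueError(f"unit must be one of {sorted(_UNIT_DIVISOR)}, got {unit!r}")
    df = pd.read_csv(path, dtype={"route_id": str}, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise RoutesFormatError(f"{path}: missing required column(s) {missing}")
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = df.index[values.isna() | (values < 0)]
    if len(bad):
        row = int(bad[0])
        raise RoutesFormatError(
            f"{path}: row {row + 2}: value {df['value'].iloc[row]!r} "
            "is negative or non-numeric"
        )
    df = df.assign(value=values / _UNIT_DIVISOR[unit])
    if df.duplicated(subset=["route_id", "seq"]).any():
        raise RoutesFormatError(f"{path}: duplicate (route_id, seq) pair")
    has_time = "timestamp" in df.columns
    has_coords = "lat" in df.columns and "lon" in df.columns
    out = []
    for rid, grp in df.groupby("route_id", sort=False):
        grp = grp.sort_values("seq")
        out.append(
            RouteSeries(
                route_id=str(rid),
                values=grp["value"].to_numpy(),
                timestamps=tuple(grp["timestamp"].astype(str)) if has_time else None,
                coords=tuple(zip(grp["lat"], grp["lon"])) if has_coords else None,
            )
        )
    return out


def write_routes_csv(routes: Iterable[RouteSeries], path) -> None:
    """Inverse of :func:`read_routes_csv` (mg/m3, 1-based seq)."""
    frames = []
    for r in routes:
        frame = pd.DataFrame(
            {"route_id": r.route_id, "seq": np.arange(1, r.n + 1), "value": r.values}
        )
        if r.timestamps is not None:
            frame["timestamp"] = list(r.timestamps)
        if r.coords is not None:
            frame["lat"] = [c[0] for c in r.coords]
            frame["lon"] = [c[1] for c in r.coords]
        frames.append(frame)
    combined = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=list(REQUIRED_COLUMNS))
    )
    combined.to_csv(path, index=False)


def _table_to_csv(table: list[dict], path: Path) -> None:
    pd.DataFrame(table).to_csv(path, index=False)


def write_report(report: dict, out_dir) -> Path:
    """Write the analysis report: ``report.json`` plus one CSV per table.

    ``report`` is the nested-dict structure produced by the pipeline; any
    key whose value is a list of row-dicts is also exported as
    ``<key>.csv``. Returns the path of the JSON file.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    json_path = out_dir / "report.json"
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
    for key, val in report.items():
        if isinstance(val, list) and val and all(isinstance(v, dict) for v in val):
            _table_to_csv(val, out_dir / f"{key}.csv")
    return json_path


def read_report(path) -> dict:
    """Read back a report written by :func:`write_report`."""
    path = Path(path)
    if path.is_dir():
        path = path / "report.json"
    with open(path) as fh:
        return json.load(fh)
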