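"""End-to-end analysis pipeline.

For each route: summary statistics, moving-average smoothing, the exact
order-statistic median confidence interval, air-quality-band
classification, the trimmed-mean location sweep and the seven-estimator
scale table; across routes: the group x band contingency table and the
one-sided rank-sum group comparison. Results are assembled into a
machine-readable report (JSON + CSV tables).

A stage that fails for one route (e.g. a sample too small for the exact
interval at the requested level) is recorded under ``errors`` with the
route id and stage name, and the pipeline continues with the remaining
routes and stages.

The per-route sign test reported alongside each interval uses the pooled
median of all analysed routes as its reference value m0 — a proxy for
the common population median under the location model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .descriptives import moving_average, summary_stats
from .io import read_routes_csv, write_report, write_routes_csv
from .nonparametric import median_ci, sign_test
from .qaqi import QAQI_BANDS, BandSystem, classify_route, compare_groups, contingency
from .robust_location import trimmed_curve
from .robust_scale import scale_table
from .series import RouteSeries
from .synthetic import StudySpec, gen_study

__all__ = ["PipelineConfig", "run_full_analysis", "load_config_file"]

log = logging.getLogger("pmroutes")


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration for :func:`run_full_analysis`.

    Exactly one of ``input_path`` / ``study_spec`` must be provided.
    Defaults: significance level 0.05, moving-average window 10, QAQI
    bands, 99-point trimming grid.
    """

    input_path: str | None = None
    study_spec: StudySpec | None = None
    unit: str = "mg_m3"
    alpha: float = 0.05
    ma_window: int = 10
    bands: BandSystem = QAQI_BANDS
    location_grid_points: int = 99
    output_dir: str | None = None
    group_of: dict[str, str] = field(default_factory=dict)
    designated_group: str = "Y"

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.study_spec is None):
            raise ValueError("provide exactly one of input_path / study_spec")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.ma_window < 1:
            raise ValueError(f"ma_window must be >= 1, got {self.ma_window}")


def _load_routes(config: PipelineConfig) -> tuple[list[RouteSeries], dict[str, str]]:
    if config.study_spec is not None:
        routes = gen_study(config.study_spec)
        groups = dict(config.study_spec.group_of)
    else:
        routes = read_routes_csv(config.input_path, unit=config.unit)
        groups = dict(config.group_of)
        if not groups:
            # default grouping: first character of the route id
            groups = {r.route_id: r.route_id[:1] for r in routes}
    return routes, groups


def run_full_analysis(config: PipelineConfig) -> dict:
    """Run every stage and return (and optionally write) the report."""
    routes, groups = _load_routes(config)
    seed = config.study_spec.seed if config.study_spec is not None else None
    report: dict = {
        "manifest": {
            "software": "pmroutes",
            "version": __version__,
            "alpha": config.alpha,
            "ma_window": config.ma_window,
            "bands": [
                {"name": b.name, "lower": b.lower, "upper": b.upper}
                for b in config.bands.bands
            ],
            "seed": seed,
            "n_routes": len(routes),
        },
        "summary": [],
        "median_ci": [],
        "classification": [],
        "scale": [],
        "location": [],
        "errors": [],
    }
    pooled = (
        np.concatenate([r.values for r in routes]) if routes else np.array([])
    )
    pooled_median = float(np.median(pooled)) if pooled.size else None
    smoothed: list[RouteSeries] = []
    labels: dict[str, str] = {}
    cis = {}

    def _stage(route_id: str, stage: str, fn):
        try:
            return fn()
        except Exception as exc:  # recorded, not fatal
            log.warning("route %s stage %s failed: %s", route_id, stage, exc)
            report["errors"].append(
                {"route": route_id, "stage": stage, "message": str(exc)}
            )
            return None

    for route in routes:
        rid = route.route_id
        log.info("route %s: %d observations", rid, route.n)
        stats = _stage(rid, "summary", lambda: summary_stats(route))
        if stats is not None:
            report["summary"].append(
                {
                    "Route": rid,
                    "Count": stats.count,
                    "Average": stats.mean,
                    "Median": stats.median,
                    "Standard Deviation": stats.sd,
                    "Skewness": stats.skewness,
                    "Kurtosis": stats.kurtosis,
                    "Minimum": stats.minimum,
                    "Maximum": stats.maximum,
                }
            )
        ma = _stage(rid, "smoothing", lambda: moving_average(route, config.ma_window))
        if ma is not None:
            smoothed.append(ma)
        ci = _stage(rid, "median_ci", lambda: median_ci(route, alpha=config.alpha))
        if ci is not None:
            cis[rid] = ci
            sign = (
                _stage(rid, "sign_test", lambda: sign_test(route, pooled_median))
                if pooled_median is not None
                else None
            )
            report["median_ci"].append(
                {
                    "Route": rid,
                    "Lower Rejection Limit": ci.lower,
                    "Upper Rejection Limit": ci.upper,
                    "Length of the Confidence Interval": ci.length,
                    "Coverage": ci.coverage,
                    "p-Value": sign.p_value if sign is not None else None,
                }
            )
            cls = _stage(rid, "classify", lambda: classify_route(ci, config.bands))
            if cls is not None:
                candidates, label = cls
                labels[rid] = label
                report["classification"].append(
                    {
                        "Route": rid,
                        "Group": groups.get(rid),
                        "Candidates": list(candidates),
                        "Label": label,
                    }
                )
        curve = _stage(
            rid,
            "location_sweep",
            lambda: trimmed_curve(route, config.location_grid_points, ci),
        )
        if curve is not None:
            report["location"].append(
                {
                    "Route": rid,
                    "Mean": curve.mean,
                    "Median": curve.median,
                    "Trimean": curve.trimean,
                }
            )
        scales = _stage(rid, "scale_table", lambda: scale_table(route))
        if scales is not None:
            report["scale"].append(
                {
                    "Route": rid,
                    "MADmean": scales.mad_mean,
                    "S": scales.sd,
                    "MAD": scales.mad,
                    "SIR": scales.sir,
                    "LMS": scales.lms,
                }
            )
        if config.output_dir is not None and curve is not None and scales is not None:
            out = Path(config.output_dir)
            out.mkdir(parents=True, exist_ok=True)
            np.savetxt(
                out / f"location_sweep_{rid}.csv",
                np.column_stack([curve.alphas, curve.estimates]),
                delimiter=",",
                header="alpha,estimate",
                comments="",
            )
            np.savetxt(
                out / f"scale_sbi_{rid}.csv",
                np.column_stack([scales.sbi_c, scales.sbi_estimates]),
                delimiter=",",
                header="c,estimate",
                comments="",
            )
            np.savetxt(
                out / f"scale_cn_{rid}.csv",
                np.column_stack([scales.cn_alphas, scales.cn_estimates]),
                delimiter=",",
                header="alpha,estimate",
                comments="",
            )

    grouped = {r: groups[r] for r in labels if r in groups}
    if labels:
        table = contingency(labels, grouped, config.bands)
        report["contingency"] = {
            "columns": list(table.columns),
            "rows": {str(idx): [int(v) for v in row] for idx, row in table.iterrows()},
        }
        try:
            cmp_res = compare_groups(
                labels, grouped, config.bands, config.designated_group
            )
            report["group_comparison"] = {
                "w": cmp_res.w,
                "expected": cmp_res.expected,
                "variance": cmp_res.variance,
                "z": cmp_res.z,
                "p_value": cmp_res.p_value,
            }
        except ValueError as exc:
            report["errors"].append(
                {"route": None, "stage": "compare_groups", "message": str(exc)}
            )
    else:
        report["contingency"] = {"columns": [], "rows": {}}

    if config.output_dir is not None:
        write_report(report, config.output_dir)
        if smoothed:
            write_routes_csv(smoothed, Path(config.output_dir) / "smoothed.csv")
    return report


def load_config_file(path) -> dict:
    """Parse a flat ``key = value`` configuration file into a dict of
    strings; blank lines and ``#`` comments are ignored."""
    out = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, _, val = line.partition("=")
        out[key.strip()] = val.strip()
    return out
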