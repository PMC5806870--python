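"""End-to-end driver: calibrate on the current map, sweep the restoration
strategies across the calibrated ensemble, and emit comparison tables.

A run is fully described by a :class:`RunConfig` (serializable to YAML) and
is deterministic given its seed.
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calibration, erosion_model, scenarios, synthetic
from .calibration import CalibrationResult, member_simulator
from .gauging import sediment_export_observed
from .raster import write_ascii_grid
from .scenarios import Scenario, StrategyCurve

__all__ = ["RunConfig", "run_pipeline", "equal_area_pick", "strategy_curves"]

logger = logging.getLogger(__name__)

GRADUAL_STRATEGIES = ("riparian", "steepest", "two_way")


@dataclass
class RunConfig:
    """Validated, serializable description of one experiment."""

    seed: int = 0
    size: str = "mini"
    observed_se: float | None = None  # default: from the bundle's gauge series
    tolerance: float = 0.10
    forest_targets: list[float] = field(
        default_factory=lambda: [5.0, 10.0, 15.0, 25.0, 35.0]
    )
    slope_bins: list[float] = field(
        default_factory=lambda: [0, 15, 30, 43, 60, 1000]
    )
    out_dir: str = "runs/out"
    write_maps: bool = False

    def __post_init__(self) -> None:
        if self.size not in synthetic.SIZES:
            raise ValueError(f"unknown watershed size {self.size!r}")
        if not 0 < self.tolerance < 1:
            raise ValueError("tolerance must be in (0, 1)")
        if list(self.forest_targets) != sorted(self.forest_targets):
            raise ValueError("forest targets must be increasing")
        if list(self.slope_bins) != sorted(self.slope_bins):
            raise ValueError("slope bin edges must be increasing")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def strategy_curves(
    bundle,
    results: list[CalibrationResult],
    targets: list[float],
) -> tuple[dict[str, StrategyCurve], pd.DataFrame]:
    """Run every gradual strategy x target x calibrated member.

    Returns the per-strategy response curves and the anthropized-baseline
    table (one row per member) the reductions are measured against.
    """
    ok = [r for r in results if r.status == "calibrated"]
    if not ok:
        raise RuntimeError("no calibrated members to run scenarios with")
    base = scenarios.anthropized(bundle.landuse)

    def simulate(scen: Scenario, res: CalibrationResult):
        shed = _ScenarioView(bundle, scen.landuse)
        out = member_simulator(shed)(res.member, res.pasture_c, res.pasture_sre)
        return out

    baseline_rows = []
    for res in ok:
        out = simulate(base, res)
        baseline_rows.append({
            "member": res.member.member_id,
            "soil_loss": out.mean_soil_loss,
            "sediment_export": out.outlet_export,
        })
    baseline = pd.DataFrame(baseline_rows)

    curves: dict[str, StrategyCurve] = {}
    for strategy in GRADUAL_STRATEGIES:
        series = scenarios.scenario_series(
            strategy, base, bundle.dist_to_stream, bundle.slope, list(targets)
        )
        rows = []
        for scen in series:
            for res in ok:
                out = simulate(scen, res)
                rows.append({
                    "scenario": scen.name,
                    "parameter": str(scen.parameter),
                    "forest_fraction": scen.forest_fraction,
                    "member": res.member.member_id,
                    "soil_loss": out.mean_soil_loss,
                    "sediment_export": out.outlet_export,
                })
        curves[strategy] = StrategyCurve(strategy, pd.DataFrame(rows))
    return curves, baseline


class _ScenarioView:
    """A watershed bundle with its land-use map swapped out."""

    def __init__(self, bundle, landuse):
        self.soilmap = bundle.soilmap
        self.erosivity = bundle.erosivity
        self.ls = bundle.ls
        self.flow = bundle.flow
        self.landuse = landuse


def equal_area_pick(
    curves: dict[str, StrategyCurve], target: float
) -> dict[str, str]:
    """Per strategy, the scenario whose forest fraction is nearest ``target``.

    Ties go to the smaller realized fraction (hence smaller parameter).
    """
    if not curves:
        raise ValueError("no strategy curves given")
    picks = {}
    for strategy, curve in curves.items():
        fracs = curve.table[["scenario", "forest_fraction"]].drop_duplicates()
        if fracs.empty:
            raise ValueError(f"strategy {strategy!r} has an empty curve")
        lo, hi = fracs["forest_fraction"].min(), fracs["forest_fraction"].max()
        if not lo - 5.0 <= target <= hi + 5.0:
            raise ValueError(
                f"target {target}% outside {strategy} curve range "
                f"[{lo:.1f}, {hi:.1f}]"
            )
        fracs = fracs.sort_values(["forest_fraction", "scenario"])
        best = fracs.iloc[
            (fracs["forest_fraction"] - target).abs().argmin()
        ]
        picks[strategy] = str(best["scenario"])
    return picks


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full experiment and write its report bundle.

    Stages: synthesize watershed -> observed export from the outlet series
    -> ensemble calibration -> strategy curves -> reductions and
    per-steepness tables.  Any stage failure removes partial outputs.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        return _run_pipeline(config, out_dir)
    except Exception:
        shutil.rmtree(out_dir, ignore_errors=True)
        raise


def _run_pipeline(config: RunConfig, out_dir: Path) -> dict:
    logger.info("stage: synthetic watershed (seed=%d size=%s)",
                config.seed, config.size)
    bundle = synthetic.make_reference_watershed(config.seed, config.size)

    logger.info("stage: observed export from outlet series")
    observed = config.observed_se
    if observed is None:
        obs = sediment_export_observed(bundle.outlet_series, bundle.area_ha)
        observed = obs.mean

    logger.info("stage: ensemble calibration (target %.3f Mg/ha/y)", observed)
    members = calibration.build_members()
    results, summary = calibration.run_ensemble(
        members, bundle, observed, tol=config.tolerance
    )
    table = calibration.results_table(results)
    table.to_csv(out_dir / "calibration.csv", index=False)

    logger.info("stage: scenario series and strategy curves")
    curves, baseline = strategy_curves(bundle, results, config.forest_targets)
    for strategy, curve in curves.items():
        curve.table.to_csv(out_dir / f"curve_{strategy}.csv", index=False)
    baseline.to_csv(out_dir / "baseline_anthropized.csv", index=False)

    comparison = scenarios.compare_strategies(curves, baseline)
    comparison.to_csv(out_dir / "strategy_comparison.csv", index=False)

    logger.info("stage: per-steepness summary at truth parameters")
    out = bundle.run_truth()
    slope_table = erosion_model.summarize_by_slope(
        out, bundle.slope, config.slope_bins
    )
    slope_table.to_csv(out_dir / "by_steepness.csv", index=False)

    if config.write_maps:
        write_ascii_grid(bundle.dem, out_dir / "dem.asc")
        write_ascii_grid(bundle.landuse, out_dir / "landuse.asc")
        write_ascii_grid(out.soil_loss, out_dir / "soil_loss.asc")
        write_ascii_grid(out.export_map, out_dir / "export_map.asc")

    report = {
        "config": asdict(config),
        "watershed": {
            "area_ha": bundle.area_ha,
            "n_cells": bundle.dem.n_valid,
            "stream_cells": int(bundle.flow.streams.sum()),
        },
        "observed_se": observed,
        "truth": asdict(bundle.truth),
        "calibration": summary,
        "strategies": {
            s: {
                "mean_export_reduction_at_max_target": float(
                    comparison[comparison.strategy == s]
                    .sort_values("forest_fraction")
                    .iloc[-1]["export_reduction_mean"]
                ),
            }
            for s in curves
        },
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
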