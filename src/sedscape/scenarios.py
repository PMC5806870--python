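"""Land-use scenario generation and restoration-strategy comparison.

All gradual strategies start from the anthropized map (remnant forest and
micro-dams removed) and add forest either within a buffer distance of the
stream network (riparian), above a slope threshold (steepest slopes), or
both with equal per-mechanism area (2-way).  Series of scenarios hitting
prescribed forest fractions are built by bisection on the strategy
parameter; strategies are compared as percent reductions of soil loss and
outlet export against a baseline, per ensemble member.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import CONVERTIBLE_CLASSES, FOREST, GROWING_FOREST, MICRODAM, PASTURE
from .raster import Raster

__all__ = [
    "Scenario",
    "StrategyCurve",
    "anthropized",
    "riparian_scenario",
    "steepest_scenario",
    "two_way_scenario",
    "scenario_series",
    "compare_strategies",
]

STRATEGIES = ("anthropized", "riparian", "steepest", "two_way", "project")


@dataclass
class Scenario:
    """A named land-use map plus the strategy and parameter that made it."""

    name: str
    landuse: Raster
    strategy: str
    parameter: float | tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")

    @property
    def forest_fraction(self) -> float:
        """Forest share of the valid watershed area, percent."""
        valid = ~self.landuse.nodata_mask
        codes = self.landuse.values[valid].astype(int)
        return 100.0 * float(
            np.isin(codes, (FOREST, GROWING_FOREST)).sum()
        ) / max(codes.size, 1)


@dataclass
class StrategyCurve:
    """Per-strategy response curve over a scenario series and the ensemble."""

    strategy: str
    table: pd.DataFrame  # columns: scenario, parameter, forest_fraction,
    #                      member, soil_loss, sediment_export


def anthropized(landuse: Raster, name: str = "anthropized") -> Scenario:
    """Counterfactual with no conservation: forest (remnant and growing)
    and micro-dams become pasture; roads, water and eucalyptus persist."""
    values = landuse.values.copy()
    codes = values.astype(int)
    convert = np.isin(codes, (FOREST, GROWING_FOREST, MICRODAM)) & ~landuse.nodata_mask
    values[convert] = PASTURE
    return Scenario(name, landuse.like(values), "anthropized")


def _convert_to_forest(landuse: Raster, where: np.ndarray) -> Raster:
    values = landuse.values.copy()
    codes = values.astype(int)
    sel = where & np.isin(codes, CONVERTIBLE_CLASSES) & ~landuse.nodata_mask
    values[sel] = FOREST
    return landuse.like(values)


def riparian_scenario(base: Scenario, dist: Raster, width: float) -> Scenario:
    """Forest every convertible cell within ``width`` metres of a stream."""
    if width < 0:
        raise ValueError(f"buffer width must be non-negative, got {width}")
    base.landuse.assert_aligned(dist, "distance-to-stream raster")
    lu = _convert_to_forest(base.landuse, dist.values <= width)
    return Scenario(f"riparian_{width:g}m", lu, "riparian", width)


def steepest_scenario(base: Scenario, slope: Raster, threshold: float) -> Scenario:
    """Forest every convertible cell steeper than ``threshold`` percent."""
    if threshold < 0:
        raise ValueError(f"slope threshold must be non-negative, got {threshold}")
    base.landuse.assert_aligned(slope, "slope raster")
    lu = _convert_to_forest(base.landuse, slope.values > threshold)
    return Scenario(f"steepest_{threshold:g}pct", lu, "steepest", threshold)


def two_way_scenario(
    base: Scenario,
    dist: Raster,
    slope: Raster,
    width: float,
    threshold: float,
) -> Scenario:
    """Union of riparian and steepest conversions at the given parameters."""
    if width < 0:
        raise ValueError(f"buffer width must be non-negative, got {width}")
    if threshold < 0:
        raise ValueError(f"slope threshold must be non-negative, got {threshold}")
    where = (dist.values <= width) | (slope.values > threshold)
    lu = _convert_to_forest(base.landuse, where)
    return Scenario(
        f"two_way_{width:g}m_{threshold:g}pct", lu, "two_way", (width, threshold)
    )


def _equal_split_two_way(
    base: Scenario, dist: Raster, slope: Raster, area_frac: float
) -> tuple[float, float]:
    """(width, threshold) whose single-mechanism conversions each cover
    ``area_frac`` (fraction of valid area) of new forest."""
    valid = ~base.landuse.nodata_mask
    codes = base.landuse.values.astype(int)
    convertible = np.isin(codes, CONVERTIBLE_CLASSES) & valid
    k = int(round(area_frac * valid.sum()))
    if k <= 0:
        return 0.0, float(slope.values.max()) + 1.0

    d = np.sort(dist.values[convertible])
    width = float(d[min(k, d.size) - 1])

    s = np.sort(slope.values[convertible])[::-1]
    kth = float(s[min(k, s.size) - 1])
    threshold = max(np.nextafter(kth, -np.inf), 0.0)  # include the k-th cell
    return width, threshold


def scenario_series(
    strategy: str,
    base: Scenario,
    dist: Raster,
    slope: Raster,
    targets: list[float],
    tol_pct: float = 0.5,
) -> list[Scenario]:
    """Scenarios whose forest fractions land within ``tol_pct`` of targets.

    The strategy parameter (buffer width, slope threshold, or the 2-way
    per-mechanism area share) is found by bisection per target.  A zero
    target returns the base scenario itself; an unreachable target raises
    with the achievable maximum.
    """
    if list(targets) != sorted(targets):
        raise ValueError("targets must be increasing")

    max_slope = float(slope.values.max()) + 1.0

    def realize(x: float) -> Scenario:
        if strategy == "riparian":
            return riparian_scenario(base, dist, x)
        if strategy == "steepest":
            # Parameterize by inverted threshold so fraction increases in x.
            return steepest_scenario(base, slope, max(max_slope - x, 0.0))
        if strategy == "two_way":
            w, t = _equal_split_two_way(base, dist, slope, x)
            return two_way_scenario(base, dist, slope, w, t)
        raise ValueError(f"unknown gradual strategy {strategy!r}")

    if strategy == "riparian":
        x_hi = float(dist.values.max()) + 1.0
    elif strategy == "steepest":
        x_hi = max_slope
    else:
        x_hi = 1.0
    max_scen = realize(x_hi)
    max_frac = max_scen.forest_fraction

    out: list[Scenario] = []
    for target in targets:
        if target <= base.forest_fraction + tol_pct:
            out.append(Scenario(base.name, base.landuse, base.strategy,
                                base.parameter))
            continue
        if target > max_frac + tol_pct:
            raise ValueError(
                f"{strategy}: target {target}% forest unreachable "
                f"(maximum {max_frac:.1f}%)"
            )
        lo, hi = 0.0, x_hi
        scen = max_scen
        for _ in range(60):
            mid = (lo + hi) / 2.0
            scen = realize(mid)
            frac = scen.forest_fraction
            if abs(frac - target) <= tol_pct:
                break
            if frac < target:
                lo = mid
            else:
                hi = mid
        if abs(scen.forest_fraction - target) > tol_pct:
            # Discreteness of the grid can leave a gap; take the closest of
            # the bracketing parameters.
            lo_s, hi_s = realize(lo), realize(hi)
            scen = min(
                (lo_s, hi_s, scen),
                key=lambda s: abs(s.forest_fraction - target),
            )
            warnings.warn(
                f"{strategy}: target {target}% realized as "
                f"{scen.forest_fraction:.2f}% (grid discreteness)"
            )
        out.append(scen)
    return out


def compare_strategies(
    curves: dict[str, StrategyCurve],
    baseline: pd.DataFrame,
) -> pd.DataFrame:
    """Percent reductions relative to a baseline run, per ensemble member.

    ``baseline`` has one row per member with ``soil_loss`` and
    ``sediment_export`` columns; reductions are
    ``100*(1 - value/baseline)``.  Returns the long-format comparison with
    ensemble mean/min/max per scenario.
    """
    if (baseline["sediment_export"] <= 0).any():
        raise ValueError("baseline sediment export must be positive")
    base = baseline.set_index("member")
    rows = []
    for strategy, curve in curves.items():
        for _, rec in curve.table.iterrows():
            b = base.loc[rec["member"]]
            rows.append({
                "strategy": strategy,
                "scenario": rec["scenario"],
                "forest_fraction": rec["forest_fraction"],
                "member": rec["member"],
                "soil_loss_reduction_pct":
                    100.0 * (1.0 - rec["soil_loss"] / b["soil_loss"]),
                "export_reduction_pct":
                    100.0 * (1.0 - rec["sediment_export"] / b["sediment_export"]),
            })
    long = pd.DataFrame(rows)
    agg = (
        long.groupby(["strategy", "scenario", "forest_fraction"])
        .agg(
            soil_loss_reduction_mean=("soil_loss_reduction_pct", "mean"),
            soil_loss_reduction_min=("soil_loss_reduction_pct", "min"),
            soil_loss_reduction_max=("soil_loss_reduction_pct", "max"),
            export_reduction_mean=("export_reduction_pct", "mean"),
            export_reduction_min=("export_reduction_pct", "min"),
            export_reduction_max=("export_reduction_pct", "max"),
        )
        .reset_index()
    )
    return agg
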