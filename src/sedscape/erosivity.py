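"""Rainfall erosivity (R factor) from multi-gauge daily precipitation.

Daily records are collapsed to a mean monthly climatology per gauge, the
twelve monthly totals are spread over the grid by single-pass Cressman
interpolation, and the erosivity map applies, per cell,

    R = 68.730 * sum_t (p_t^2 / P)^0.841      [MJ mm ha^-1 h^-1 y^-1]

with p_t the mean monthly rainfall (mm) and P the mean annual total (mm).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import Raster

__all__ = [
    "RainGaugeSeries",
    "MonthlyClimatology",
    "monthly_climatology",
    "cressman_interpolate",
    "erosivity_map",
    "erosivity_from_gauges",
    "EROSIVITY_COEF",
    "EROSIVITY_EXP",
]

logger = logging.getLogger(__name__)

EROSIVITY_COEF = 68.730
EROSIVITY_EXP = 0.841


@dataclass
class RainGaugeSeries:
    """Daily precipitation at one gauge, located in grid coordinates (m)."""

    gauge_id: str
    location: tuple[float, float]
    daily_precip: pd.Series  # DatetimeIndex -> mm

    def __post_init__(self) -> None:
        s = self.daily_precip
        if not isinstance(s.index, pd.DatetimeIndex):
            raise TypeError("daily_precip must be indexed by dates")
        if s.index.has_duplicates:
            raise ValueError(f"gauge {self.gauge_id}: duplicate dates")
        if (s.dropna() < 0).any():
            raise ValueError(f"gauge {self.gauge_id}: negative precipitation")


@dataclass
class MonthlyClimatology:
    """Mean monthly totals p_t (mm, t=1..12) and their annual sum."""

    gauge_id: str
    monthly: np.ndarray  # shape (12,)

    def __post_init__(self) -> None:
        self.monthly = np.asarray(self.monthly, dtype=float)
        if self.monthly.shape != (12,):
            raise ValueError("monthly climatology needs exactly 12 values")
        if (self.monthly < 0).any():
            raise ValueError("negative monthly totals")

    @property
    def annual(self) -> float:
        return float(self.monthly.sum())


def monthly_climatology(
    series: RainGaugeSeries,
    start: str | pd.Timestamp,
    end: str | pd.Timestamp,
) -> MonthlyClimatology:
    """Calendar-month mean totals over [start, end]; missing days count as 0.

    Each calendar month's climatological total is the mean, over the years
    covered, of that month's summed daily precipitation.  Days absent from
    the record contribute zero and are tallied in a logged warning.
    """
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    if end < start:
        raise ValueError(f"empty period: {start.date()} .. {end.date()}")
    if (end - start).days < 334:
        raise ValueError("period shorter than 12 months")
    window = series.daily_precip.loc[start:end].dropna()
    full_index = pd.date_range(start, end, freq="D")
    n_missing = len(full_index) - len(window)
    if n_missing > 0:
        logger.warning(
            "gauge %s: %d missing day(s) in %s..%s treated as 0 mm",
            series.gauge_id, n_missing, start.date(), end.date(),
        )
    filled = window.reindex(full_index, fill_value=0.0)
    by_month = filled.groupby([filled.index.year, filled.index.month]).sum()
    monthly = np.zeros(12)
    for t in range(1, 13):
        vals = by_month.xs(t, level=1) if t in by_month.index.get_level_values(1) else None
        monthly[t - 1] = float(vals.mean()) if vals is not None and len(vals) else 0.0
    return MonthlyClimatology(series.gauge_id, monthly)


def cressman_interpolate(
    values: np.ndarray,
    locations: np.ndarray,
    grid: Raster,
    radius: float,
) -> Raster:
    """Single-pass Cressman-weighted mean of gauge values on the grid.

    Weights are ``w = (R^2 - d^2)/(R^2 + d^2)`` for gauge distance ``d < R``
    and zero beyond.  Cells with no gauge inside the radius fall back to
    inverse-distance weighting over all gauges (logged).
    """
    if radius <= 0:
        raise ValueError(f"Cressman radius must be positive, got {radius}")
    values = np.asarray(values, dtype=float)
    locations = np.asarray(locations, dtype=float)
    if values.shape[0] != locations.shape[0]:
        raise ValueError("one value per gauge location required")
    gx, gy = grid.cell_coords()
    d2 = (
        (gx[..., None] - locations[:, 0]) ** 2
        + (gy[..., None] - locations[:, 1]) ** 2
    )
    r2 = radius * radius
    w = np.where(d2 < r2, (r2 - d2) / (r2 + d2), 0.0)
    wsum = w.sum(axis=-1)
    covered = wsum > 0
    out = np.zeros(grid.shape)
    with np.errstate(invalid="ignore", divide="ignore"):
        out[covered] = (w @ values)[covered] / wsum[covered]
    if not covered.all():
        n = int((~covered & ~grid.nodata_mask).sum())
        if n:
            logger.warning(
                "%d cell(s) outside Cressman radius of every gauge; "
                "falling back to inverse-distance weighting", n,
            )
        widw = 1.0 / np.maximum(d2, 1e-12)
        out[~covered] = (widw @ values)[~covered] / widw.sum(axis=-1)[~covered]
    return grid.like(out)


def erosivity_map(monthly_maps: list[Raster]) -> Raster:
    """Per-cell R factor from twelve aligned monthly precipitation maps."""
    if len(monthly_maps) != 12:
        raise ValueError(f"need 12 monthly maps, got {len(monthly_maps)}")
    ref = monthly_maps[0]
    for i, m in enumerate(monthly_maps[1:], start=2):
        ref.assert_aligned(m, f"monthly map {i}")
        if (m.values[~m.nodata_mask] < 0).any():
            raise ValueError(f"monthly map {i} has negative precipitation")
    stack = np.stack([m.values for m in monthly_maps])
    annual = stack.sum(axis=0)
    zero = annual <= 0
    if zero.any() and (~ref.nodata_mask & zero).any():
        warnings.warn("cells with zero annual precipitation get R = 0")
    safe_annual = np.where(zero, 1.0, annual)
    r = EROSIVITY_COEF * np.sum(
        (stack**2 / safe_annual) ** EROSIVITY_EXP, axis=0
    )
    r[zero] = 0.0
    return ref.like(r)


def erosivity_from_gauges(
    gauges: list[RainGaugeSeries],
    grid: Raster,
    start: str | pd.Timestamp,
    end: str | pd.Timestamp,
    radius: float | None = None,
) -> Raster:
    """Full chain: climatology per gauge, Cressman per month, then R map.

    When ``radius`` is omitted it defaults to 1.2 times the largest
    cell-to-nearest-gauge distance, so every grid cell sees at least one
    gauge and the inverse-distance fallback stays unused.
    """
    if not gauges:
        raise ValueError("at least one rain gauge required")
    clims = [monthly_climatology(g, start, end) for g in gauges]
    locs = np.array([g.location for g in gauges], dtype=float)
    if radius is None:
        radius = _default_radius(locs, grid)
    maps = []
    for t in range(12):
        vals = np.array([c.monthly[t] for c in clims])
        maps.append(cressman_interpolate(vals, locs, grid, radius))
    return erosivity_map(maps)


def _default_radius(locations: np.ndarray, grid: Raster) -> float:
    gx, gy = grid.cell_coords()
    d2 = (
        (gx[..., None] - locations[:, 0]) ** 2
        + (gy[..., None] - locations[:, 1]) ** 2
    )
    return 1.2 * float(np.sqrt(d2.min(axis=-1).max()))
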