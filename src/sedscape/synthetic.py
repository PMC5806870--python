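"""Fully synthetic watershed bundles with known generating parameters.

Every pipeline stage can be exercised offline: a ridge-to-valley DEM, soil
and land-use class maps honouring target class fractions, five rain gauges
with seasonal daily precipitation, and a twice-daily outlet series whose
implied sediment export matches the forward model run with the bundle's
"true" parameter set exactly.  All randomness flows through one seeded
generator, so a seed fully determines a bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import erosion_model, gauging, terrain
from .calibration import CalibrationMember, member_simulator
from .erosivity import RainGaugeSeries, erosivity_from_gauges
from .gauging import DEFAULT_TURBIDITY_CURVE, GaugeSeries, suspended_sediment
from .params import (
    EUCALYPTUS,
    FOREST,
    GROWING_FOREST,
    MICRODAM,
    PASTURE,
    ROAD,
    SOIL_CODES,
    C_RANGES,
    FOREST_SRE_OPTIONS,
    PASTURE_SRE_RANGE,
)
from .raster import Raster

__all__ = [
    "TruthParams",
    "WatershedBundle",
    "make_dem",
    "make_soils",
    "make_landuse",
    "make_outlet_series",
    "make_reference_watershed",
    "DEFAULT_FRACTIONS",
    "SIZES",
]

# Target land-use fractions for the "current" map.
DEFAULT_FRACTIONS: dict[int, float] = {
    PASTURE: 0.709,
    FOREST: 0.22,
    GROWING_FOREST: 0.03,
    ROAD: 0.02,
    EUCALYPTUS: 0.02,
    MICRODAM: 0.001,
}

# (ny, nx, stream threshold): full reproduces a 1200 ha basin at 5 m;
# mini is a 4096-cell variant for fast tests, threshold scaled with area.
SIZES: dict[str, tuple[int, int, int]] = {
    "full": (693, 693, 2000),
    "mini": (64, 64, 60),
}

HYDRO_YEARS = ("2010-10-01", "2015-09-30")


@dataclass
class TruthParams:
    """Generating parameter set of a synthetic bundle."""

    k_option: str
    forest_sre: float
    linkage: str
    pasture_c: float
    pasture_sre: float
    observed_se: float = float("nan")  # filled once the forward model runs

    def as_member(self) -> CalibrationMember:
        return CalibrationMember(
            member_id="truth",
            k_option=self.k_option,
            forest_sre=self.forest_sre,
            initial_pasture_c="min",
            linkage=self.linkage,
        )


@dataclass
class WatershedBundle:
    """Everything one run of the pipeline needs, plus the generating truth."""

    dem: Raster
    filled_dem: Raster
    flow: terrain.FlowField
    slope: Raster
    ls: Raster
    dist_to_stream: Raster
    soilmap: Raster
    landuse: Raster
    erosivity: Raster
    gauges: list[RainGaugeSeries]
    outlet_series: GaugeSeries
    truth: TruthParams
    seed: int
    size: str

    @property
    def area_ha(self) -> float:
        return self.dem.valid_area_ha

    def run_truth(self) -> erosion_model.SedimentOutputs:
        """Forward model at the truth parameters."""
        run = member_simulator(self)
        return run(self.truth.as_member(), self.truth.pasture_c,
                   self.truth.pasture_sre)


def make_dem(
    nx: int,
    ny: int,
    cell_size: float = 5.0,
    relief: float | None = None,
    roughness: float = 1.0,
    seed: int = 0,
) -> Raster:
    """Ridge-to-valley synthetic DEM draining to the bottom edge.

    A south-tilted plane carries the base relief (default 22% of the
    north-south extent, a steep basin); ``roughness`` scales a cross-valley
    bowl plus a band-limited random field, spreading the percent-slope
    distribution from near 0 to beyond 60%.  ``roughness=0`` returns the
    bare plane (slope = relief / north-south extent).
    """
    if nx < 16 or ny < 16:
        raise ValueError("DEM must be at least 16x16")
    if relief is None:
        relief = 0.22 * (ny - 1) * cell_size
    rng = np.random.default_rng(seed)
    rows = np.arange(ny)[:, None] / (ny - 1)
    cols = np.arange(nx)[None, :] / (nx - 1)
    # Roughness morphs the plane into an incised valley: the tilt flattens
    # while the cross-valley bowl and noise grow, so valley bottoms stay
    # gentler than the hillslopes (as in a real stream-cut basin).
    base = (1.0 - 0.65 * roughness) * relief * (1.0 - rows)
    valley = 0.65 * relief * (2.0 * cols - 1.0) ** 2
    noise = rng.standard_normal((ny, nx))
    noise = ndimage.gaussian_filter(noise, sigma=max(nx, ny) / 10.0)
    noise = noise / max(noise.std(), 1e-12)
    z = base + roughness * (valley + 0.12 * relief * noise)
    return Raster(z, cell_size)


def make_soils(
    grid: Raster,
    seed: int = 0,
    streams: np.ndarray | None = None,
    n_patches: int = 24,
) -> Raster:
    """Contiguous random soil patches; Fluvent placed along the streams.

    Patches are nearest-seed (Voronoi) regions labelled cyclically with the
    five soil classes.  When a stream mask is supplied, cells within two
    cells of a stream become Fluvent (code 5).
    """
    codes = sorted(SOIL_CODES)
    rng = np.random.default_rng(seed)
    ny, nx = grid.shape
    pts = np.column_stack([rng.integers(0, ny, n_patches),
                           rng.integers(0, nx, n_patches)])
    labels = np.array([codes[i % len(codes)] for i in range(n_patches)])
    rng.shuffle(labels)
    rr, cc = np.mgrid[0:ny, 0:nx]
    d2 = (rr[..., None] - pts[:, 0]) ** 2 + (cc[..., None] - pts[:, 1]) ** 2
    soil = labels[d2.argmin(axis=-1)].astype(float)
    if streams is not None and streams.any():
        near = ndimage.binary_dilation(streams, iterations=2)
        soil[near] = 5  # fluvent
    return grid.like(soil)


def make_landuse(
    grid: Raster,
    streams: np.ndarray,
    slope: Raster,
    fractions: dict[int, float] | None = None,
    seed: int = 0,
) -> Raster:
    """Land-use map hitting target class fractions within 1%.

    Roads are connected polylines crossing the basin; micro-dams sit on
    cells adjacent to roads; forest occupies the cells scoring highest on a
    mix of stream proximity and steepness (with a random component, so
    patches look organic); growing forest rings the forest; eucalyptus is
    one compact patch; everything else is pasture.
    """
    fractions = dict(fractions or DEFAULT_FRACTIONS)
    if sum(fractions.values()) > 1.0 + 1e-9:
        raise ValueError(f"class fractions sum to {sum(fractions.values()):.3f} > 1")
    rng = np.random.default_rng(seed)
    ny, nx = grid.shape
    n = ny * nx
    lu = np.full((ny, nx), PASTURE, dtype=float)

    # Roads: one sinuous horizontal and one vertical polyline, thickened
    # until the road budget is met.
    road = np.zeros((ny, nx), dtype=bool)
    amp = max(ny // 10, 1)
    xs = np.arange(nx)
    r0 = (ny // 3 + amp * np.sin(2 * np.pi * xs / nx * 2)).astype(int).clip(0, ny - 1)
    road[r0, xs] = True
    ys = np.arange(ny)
    c0 = (nx // 4 + amp * np.cos(2 * np.pi * ys / ny * 1.5)).astype(int).clip(0, nx - 1)
    road[ys, c0] = True
    target_road = int(round(fractions.get(ROAD, 0.0) * n))
    while road.sum() < target_road:
        road = ndimage.binary_dilation(road)
    # Trim overshoot deterministically.
    excess = int(road.sum()) - target_road
    if excess > 0:
        idx = np.nonzero(road.ravel())[0]
        road.ravel()[rng.choice(idx, size=excess, replace=False)] = False
    lu[road] = ROAD

    # Micro-dams: road-adjacent cells.
    target_dam = max(int(round(fractions.get(MICRODAM, 0.0) * n)), 1)
    ring = ndimage.binary_dilation(road) & ~road
    ring_idx = np.nonzero(ring.ravel())[0]
    dam_idx = rng.choice(ring_idx, size=min(target_dam, ring_idx.size),
                         replace=False)
    lu.ravel()[dam_idx] = MICRODAM

    # Forest: remnant patches live mostly on steep ground with a mild
    # riparian pull (restoration corridors), plus noise for organic shapes.
    dist = ndimage.distance_transform_edt(~streams, sampling=grid.cell_size)
    s = slope.values
    score = (
        1.2 * s / max(s.max(), 1e-9)
        + 0.25 * np.exp(-dist / (6.0 * grid.cell_size))
        + 0.3 * ndimage.gaussian_filter(rng.standard_normal((ny, nx)), 3)
    )
    score[lu != PASTURE] = -np.inf
    target_forest = int(round(fractions.get(FOREST, 0.0) * n))
    order = np.argsort(score.ravel())[::-1]
    lu.ravel()[order[:target_forest]] = FOREST

    # Growing forest: the next-best ring of cells after remnant forest.
    target_grow = int(round(fractions.get(GROWING_FOREST, 0.0) * n))
    if target_grow:
        lu.ravel()[order[target_forest:target_forest + target_grow]] = GROWING_FOREST

    # Eucalyptus: one compact blob grown from a random pasture cell.
    target_euc = int(round(fractions.get(EUCALYPTUS, 0.0) * n))
    if target_euc:
        pasture_idx = np.nonzero((lu == PASTURE).ravel())[0]
        centre = rng.choice(pasture_idx)
        cy, cx = divmod(int(centre), nx)
        rr, cc = np.mgrid[0:ny, 0:nx]
        d2 = (rr - cy) ** 2 + (cc - cx) ** 2
        d2[lu != PASTURE] = np.iinfo(np.int64).max
        blob = np.argsort(d2.ravel())[:target_euc]
        lu.ravel()[blob] = EUCALYPTUS

    return grid.like(lu)


def make_rain_gauges(
    grid: Raster,
    seed: int = 0,
    n_gauges: int = 5,
    annual_mm: float = 1500.0,
    start: str = HYDRO_YEARS[0],
    end: str = HYDRO_YEARS[1],
) -> list[RainGaugeSeries]:
    """Five gauges with seasonal daily rainfall (~``annual_mm`` per year)."""
    rng = np.random.default_rng(seed)
    ny, nx = grid.shape
    x0, y0 = grid.origin
    dates = pd.date_range(start, end, freq="D")
    doy = dates.day_of_year.to_numpy()
    # Wet summers (DJF peak), dry winters.
    season = 1.0 + 0.9 * np.cos(2 * np.pi * (doy - 15) / 365.25)
    p_wet = np.clip(0.18 * season, 0.02, 0.6)
    gauges = []
    for g in range(n_gauges):
        loc = (
            x0 + rng.uniform(0.1, 0.9) * (nx - 1) * grid.cell_size,
            y0 - rng.uniform(0.1, 0.9) * (ny - 1) * grid.cell_size,
        )
        wet = rng.random(dates.size) < p_wet
        amounts = rng.gamma(1.2, 10.0, size=dates.size) * season
        precip = np.where(wet, amounts * rng.uniform(0.9, 1.1), 0.0)
        # Normalize so the mean annual total is on target for this gauge.
        years = (dates.max() - dates.min()).days / 365.25
        precip *= annual_mm * years / max(precip.sum(), 1e-9)
        gauges.append(RainGaugeSeries(
            gauge_id=f"P{g + 1}",
            location=loc,
            daily_precip=pd.Series(precip, index=dates),
        ))
    return gauges


def make_outlet_series(
    target_se: float,
    drainage_area_ha: float,
    years: int = 5,
    noise_sd: float = 0.0,
    seed: int = 0,
    start: str = HYDRO_YEARS[0],
) -> GaugeSeries:
    """Twice-daily outlet discharge/turbidity whose implied export matches.

    Discharge mixes a seasonal baseflow with lognormal storm peaks;
    turbidity comes from the packaged rating curve times multiplicative
    lognormal noise of spread ``noise_sd``.  The discharge is then rescaled
    so the mean annual sediment export implied by the realized series
    equals ``target_se`` exactly (so a bundle's truth closes through the
    gauging equations as well as the routing model).
    """
    if years < 1:
        raise ValueError("need at least one year of records")
    rng = np.random.default_rng(seed)
    idx = pd.date_range(start, periods=years * 730, freq="12h")
    doy = idx.day_of_year.to_numpy()
    season = 1.0 + 0.8 * np.cos(2 * np.pi * (doy - 15) / 365.25)
    base = 0.12 * season
    storms = rng.lognormal(mean=-1.5, sigma=1.1, size=idx.size) * (
        rng.random(idx.size) < 0.08 * season
    )
    q = base + storms
    tu_noise = (
        rng.lognormal(mean=-0.5 * noise_sd**2, sigma=noise_sd, size=idx.size)
        if noise_sd > 0 else np.ones(idx.size)
    )

    def mean_se(alpha: float) -> float:
        qs = alpha * q
        tu = DEFAULT_TURBIDITY_CURVE(qs) * tu_noise
        ss = suspended_sediment(tu)
        inst = pd.Series(
            gauging.FLUX_UNIT_FACTOR * qs * ss / drainage_area_ha, index=idx
        )
        annual = inst.groupby(gauging.hydrological_year(idx)).mean()
        return float(annual.mean())

    from scipy.optimize import brentq

    lo, hi = 1e-3, 1.0
    while mean_se(hi) < target_se:
        hi *= 2.0
        if hi > 1e4:
            raise RuntimeError("cannot scale discharge to reach target export")
    alpha = brentq(lambda a: mean_se(a) - target_se, lo, hi, xtol=1e-12)
    qs = alpha * q
    tu = DEFAULT_TURBIDITY_CURVE(qs) * tu_noise
    frame = pd.DataFrame(
        {"discharge": qs, "turbidity": tu, "ss": suspended_sediment(tu)},
        index=idx,
    )
    return GaugeSeries(frame)


def make_reference_watershed(
    seed: int = 0,
    size: str = "mini",
    truth: TruthParams | None = None,
    noise_sd: float = 0.0,
) -> WatershedBundle:
    """One-call bundle: terrain, soils, land use, rain, outlet truth.

    ``size`` is ``"mini"`` (64x64, fast) or ``"full"`` (1200 ha at 5 m).
    When ``truth`` is omitted, the generating parameters are drawn from the
    packaged calibration ranges with the bundle's generator.
    """
    if size not in SIZES:
        raise ValueError(f"size must be one of {sorted(SIZES)}, got {size!r}")
    ny, nx, threshold = SIZES[size]
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31, size=6)

    dem = make_dem(nx, ny, seed=int(sub[0]))
    filled = terrain.fill_depressions(dem)
    flow = terrain.d8_flow(filled, threshold=threshold)
    slope = terrain.slope_percent(filled)
    ls = terrain.ls_factor(flow, slope)
    dist = terrain.distance_to_stream(flow.streams, dem.cell_size)
    soil = make_soils(dem, seed=int(sub[1]), streams=flow.streams)
    landuse = make_landuse(dem, flow.streams, slope, seed=int(sub[2]))
    gauges = make_rain_gauges(dem, seed=int(sub[3]))
    r = erosivity_from_gauges(gauges, dem, *HYDRO_YEARS)

    if truth is None:
        # Drawn from the calibration ranges, but kept in the upper-C /
        # lower-SRE region so the target export is demanding: members then
        # calibrate at interior pasture C with forest C below pasture C,
        # mirroring the structure of a real calibration table.
        p_lo, p_hi = C_RANGES["pasture"]
        truth = TruthParams(
            k_option=str(rng.choice(["mean", "max"])),
            forest_sre=float(rng.choice(FOREST_SRE_OPTIONS)),
            linkage=str(rng.choice(["increasing", "decreasing"])),
            pasture_c=float(rng.uniform(0.5 * (p_lo + p_hi), p_hi)),
            pasture_sre=float(rng.uniform(PASTURE_SRE_RANGE[0], 0.15)),
        )

    bundle = WatershedBundle(
        dem=dem, filled_dem=filled, flow=flow, slope=slope, ls=ls,
        dist_to_stream=dist, soilmap=soil, landuse=landuse, erosivity=r,
        gauges=gauges, outlet_series=None, truth=truth, seed=seed, size=size,
    )
    out = bundle.run_truth()
    truth.observed_se = out.outlet_export
    bundle.outlet_series = make_outlet_series(
        truth.observed_se, dem.valid_area_ha, noise_sd=noise_sd,
        seed=int(sub[4]),
    )
    return bundle
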