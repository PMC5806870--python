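"""Outlet-gauge processing: rating curves and observed sediment export.

Stage is converted to discharge by a fitted power rating curve, discharge to
turbidity by a piecewise rating curve (power segments with a final linear
segment), turbidity to suspended-sediment concentration by a linear
relation, and the instantaneous fluxes are aggregated to annual and
period-mean sediment export per unit drainage area.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "RatingSegment",
    "RatingCurve",
    "GaugeSeries",
    "ObservedExport",
    "DEFAULT_TURBIDITY_CURVE",
    "fit_stage_discharge",
    "fit_turbidity_curve",
    "turbidity_from_discharge",
    "suspended_sediment",
    "sediment_export_observed",
    "frequency_distribution",
    "SS_SLOPE",
    "SS_INTERCEPT",
    "FLUX_UNIT_FACTOR",
]

logger = logging.getLogger(__name__)

# Suspended sediment (mg/L) from turbidity (NTU): SS = 1.114*TU + 1.4731.
SS_SLOPE = 1.114
SS_INTERCEPT = 1.4731

# Mg ha^-1 y^-1 from (m^3 s^-1)*(mg L^-1)/ha: 31.536e6 s/y * 1e-6 Mg/(mg m^-3 * m^3).
FLUX_UNIT_FACTOR = 31.536


@dataclass(frozen=True)
class RatingSegment:
    """One branch of a rating curve on the half-open domain [q_lo, q_hi).

    ``form`` is ``"power"`` (a*Q**b) or ``"linear"`` (a*Q + c).
    """

    q_lo: float
    q_hi: float
    form: str
    a: float
    b: float = 1.0
    c: float = 0.0

    def __call__(self, q: np.ndarray) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        if self.form == "power":
            with np.errstate(invalid="ignore"):
                out = self.a * q**self.b
            return np.where(q == 0, 0.0 if self.b > 0 else self.a, out)
        if self.form == "linear":
            return self.a * q + self.c
        raise ValueError(f"unknown segment form {self.form!r}")


@dataclass(frozen=True)
class RatingCurve:
    """Ordered segments partitioning [0, inf); evaluation clamps at zero."""

    segments: tuple[RatingSegment, ...]

    def __post_init__(self) -> None:
        segs = self.segments
        if not segs:
            raise ValueError("rating curve needs at least one segment")
        if segs[0].q_lo != 0 or not np.isinf(segs[-1].q_hi):
            raise ValueError("segments must cover [0, inf)")
        for lo, hi in zip(segs[:-1], segs[1:]):
            if lo.q_hi != hi.q_lo:
                raise ValueError("segment domains must be contiguous")

    def __call__(self, q):
        q = np.asarray(q, dtype=float)
        scalar = q.ndim == 0
        q = np.atleast_1d(q)
        out = np.zeros_like(q)
        for seg in self.segments:
            sel = (q >= seg.q_lo) & (q < seg.q_hi)
            out[sel] = seg(q[sel])
        out = np.clip(out, 0.0, None)
        return float(out[0]) if scalar else out


#: Packaged turbidity-discharge curve (NTU from m^3/s):
#: 94.58*Q^1.14 below 0.23; 308.92*Q^1.90 on [0.23, 0.95); 560.42*Q - 252.3 above.
DEFAULT_TURBIDITY_CURVE = RatingCurve((
    RatingSegment(0.0, 0.23, "power", 94.58, 1.14),
    RatingSegment(0.23, 0.95, "power", 308.92, 1.90),
    RatingSegment(0.95, np.inf, "linear", 560.42, c=-252.3),
))


@dataclass
class GaugeSeries:
    """Timestamped outlet records; discharge required, the rest optional."""

    frame: pd.DataFrame  # columns: discharge, optional stage/turbidity/ss

    def __post_init__(self) -> None:
        df = self.frame
        if "discharge" not in df.columns:
            raise ValueError("gauge series needs a 'discharge' column")
        if not isinstance(df.index, pd.DatetimeIndex):
            raise TypeError("gauge series must be indexed by timestamps")
        if not df.index.is_monotonic_increasing or df.index.has_duplicates:
            raise ValueError("timestamps must be strictly increasing")
        for col in ("discharge", "turbidity", "ss"):
            if col in df.columns and (df[col].dropna() < 0).any():
                raise ValueError(f"negative values in {col!r}")


@dataclass
class ObservedExport:
    """Observed sediment export: annual series and its period mean."""

    drainage_area_ha: float
    annual: pd.Series  # hydrological-year label -> Mg ha^-1 y^-1
    mean: float
    instantaneous: pd.Series | None = None


@dataclass(frozen=True)
class StageDischargeCurve:
    """Q = a*(h - h0)^b, clamped to zero at or below the offset stage h0."""

    a: float
    b: float
    h0: float

    def __call__(self, stage):
        stage = np.asarray(stage, dtype=float)
        scalar = stage.ndim == 0
        stage = np.atleast_1d(stage)
        q = np.where(stage > self.h0, self.a * np.maximum(stage - self.h0, 0) ** self.b, 0.0)
        return float(q[0]) if scalar else q


def fit_stage_discharge(pairs: list[tuple[float, float]]) -> StageDischargeCurve:
    """Least-squares power rating Q = a*(h-h0)^b from (stage, Q) pairs.

    The offset h0 is profiled by 1-D minimisation; for each candidate the
    (a, b) pair is the exact log-linear least-squares solution.
    """
    if len(pairs) < 4:
        raise ValueError(f"need at least 4 stage-discharge pairs, got {len(pairs)}")
    arr = np.array(sorted(pairs), dtype=float)
    h, q = arr[:, 0], arr[:, 1]
    if len(np.unique(h)) != len(h):
        raise ValueError("stages must be distinct")
    if (np.diff(q) < 0).any():
        bad = [tuple(arr[i + 1]) for i in np.nonzero(np.diff(q) < 0)[0]]
        raise ValueError(f"discharge not monotone in stage at pairs {bad}")
    if (q <= 0).any():
        raise ValueError("discharges must be positive for a log-scale fit")

    def sse(h0: float) -> float:
        a, b = _loglinear(h - h0, q)
        return float(((a * (h - h0) ** b - q) ** 2).sum())

    hi = h.min() - 1e-9
    lo = h.min() - (h.max() - h.min())
    res = optimize.minimize_scalar(sse, bounds=(lo, hi), method="bounded")
    h0 = float(res.x)
    a, b = _loglinear(h - h0, q)
    return StageDischargeCurve(a=a, b=b, h0=h0)


def _loglinear(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact least squares of log y = log a + b log x."""
    b, loga = np.polyfit(np.log(x), np.log(y), 1)
    return float(np.exp(loga)), float(b)


def fit_turbidity_curve(
    pairs: list[tuple[float, float]] | None = None,
    breakpoints: tuple[float, ...] = (0.23, 0.95),
) -> RatingCurve:
    """Piecewise turbidity rating from (Q, TU) pairs.

    Every segment but the last is fitted as a power law on log scale; the
    last (highest-discharge) segment is linear.  With no pairs the packaged
    default curve is returned.
    """
    if pairs is None:
        return DEFAULT_TURBIDITY_CURVE
    arr = np.array(pairs, dtype=float)
    edges = (0.0, *breakpoints, np.inf)
    segments = []
    for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        sel = (arr[:, 0] >= lo) & (arr[:, 0] < hi)
        q, tu = arr[sel, 0], arr[sel, 1]
        if len(q) < 2:
            raise ValueError(
                f"segment [{lo}, {hi}) has {len(q)} pair(s); need at least 2"
            )
        last = i == len(edges) - 2
        if last:
            a, c = np.polyfit(q, tu, 1)
            segments.append(RatingSegment(lo, hi, "linear", float(a), c=float(c)))
        else:
            a, b = _loglinear(q, tu)
            segments.append(RatingSegment(lo, hi, "power", a, b))
    return RatingCurve(tuple(segments))


def turbidity_from_discharge(q, curve: RatingCurve = DEFAULT_TURBIDITY_CURVE):
    """Turbidity (NTU) from discharge (m^3/s) via a rating curve."""
    return curve(q)


def suspended_sediment(tu):
    """Suspended-sediment concentration (mg/L) from turbidity (NTU)."""
    tu = np.asarray(tu, dtype=float)
    out = SS_SLOPE * tu + SS_INTERCEPT
    return float(out) if out.ndim == 0 else out


def hydrological_year(timestamps: pd.DatetimeIndex) -> np.ndarray:
    """Label each timestamp with its Oct-Sep hydrological year (end year)."""
    return timestamps.year + (timestamps.month >= 10).astype(int)


def sediment_export_observed(
    series: GaugeSeries,
    drainage_area_ha: float,
    curve: RatingCurve = DEFAULT_TURBIDITY_CURVE,
) -> ObservedExport:
    """Observed sediment export from a discharge (or discharge+SS) series.

    Instantaneous export is ``31.536 * Q * SS / DA`` (Mg ha^-1 y^-1 as a
    rate); each Oct-Sep hydrological year's value is the mean of its
    instantaneous rates, and the period mean averages the annual values.
    Missing turbidity/SS columns are synthesised through the rating curve
    and the turbidity-sediment relation.
    """
    if drainage_area_ha <= 0:
        raise ValueError(f"drainage area must be positive, got {drainage_area_ha}")
    df = series.frame
    q = df["discharge"].to_numpy(dtype=float)
    if "ss" in df.columns and df["ss"].notna().all():
        ss = df["ss"].to_numpy(dtype=float)
    else:
        if "turbidity" in df.columns and df["turbidity"].notna().all():
            tu = df["turbidity"].to_numpy(dtype=float)
        else:
            tu = turbidity_from_discharge(q, curve)
        ss = suspended_sediment(tu)
    inst = pd.Series(
        FLUX_UNIT_FACTOR * q * ss / drainage_area_ha, index=df.index, name="se"
    )
    years = hydrological_year(df.index)
    annual = inst.groupby(years).mean()
    empty = annual.isna()
    if empty.any():
        logger.warning("skipping %d empty hydrological year(s)", int(empty.sum()))
        annual = annual[~empty]
    annual.index = annual.index.astype(int)
    return ObservedExport(
        drainage_area_ha=drainage_area_ha,
        annual=annual,
        mean=float(annual.mean()),
        instantaneous=inst,
    )


def frequency_distribution(
    values: np.ndarray, bins: int | np.ndarray = 10
) -> pd.DataFrame:
    """Percentage histogram of a variable; percentages sum to 100."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty series")
    counts, edges = np.histogram(values, bins=bins)
    if (np.diff(edges) <= 0).any():
        raise ValueError("zero-width histogram bin")
    return pd.DataFrame({
        "bin_lo": edges[:-1],
        "bin_hi": edges[1:],
        "count": counts,
        "percent": 100.0 * counts / counts.sum(),
    })
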