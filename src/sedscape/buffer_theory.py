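"""Buffer trapping efficiency versus per-cell sediment retention efficiency.

A vegetation strip of width ``l`` on a grid of cell size ``r`` spans
``n = l/r`` cells.  With a homogeneous per-cell retention efficiency
``SRE`` and no erosion inside the strip, the mass surviving the strip is
``(1-SRE)^n``, so the whole-buffer trapping efficiency is

    Te = 1 - (1 - SRE)^(l/r)

and the relation inverts exactly.  A band of SRE values can be fitted to
literature width-trapping points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "BufferSpec",
    "TrappingPoint",
    "trapping_from_sre",
    "sre_from_trapping",
    "fit_sre_band",
    "load_literature_points",
]


@dataclass(frozen=True)
class BufferSpec:
    """A homogeneous buffer: per-cell retention, width, and cell size."""

    sre: float
    width: float
    pixel: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.sre <= 1.0:
            raise ValueError(f"SRE must be in [0, 1], got {self.sre}")
        if self.width < 0:
            raise ValueError(f"width must be non-negative, got {self.width}")
        if self.pixel <= 0:
            raise ValueError(f"pixel size must be positive, got {self.pixel}")

    @property
    def n_cells(self) -> float:
        return self.width / self.pixel


@dataclass(frozen=True)
class TrappingPoint:
    width: float
    te: float
    source: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.te <= 1.0:
            raise ValueError(f"trapping efficiency must be in [0, 1], got {self.te}")


def trapping_from_sre(spec: BufferSpec) -> float:
    """Whole-buffer trapping efficiency Te = 1 - (1-SRE)^(l/r)."""
    return float(1.0 - (1.0 - spec.sre) ** spec.n_cells)


def sre_from_trapping(te: float, width: float, pixel: float) -> float:
    """Per-cell retention from a buffer's trapping efficiency (exact inverse)."""
    if not 0.0 <= te < 1.0:
        raise ValueError(
            f"trapping efficiency must be in [0, 1) for a finite buffer, got {te}"
        )
    if width <= 0:
        raise ValueError(f"width must be positive, got {width}")
    if pixel <= 0:
        raise ValueError(f"pixel size must be positive, got {pixel}")
    return float(1.0 - (1.0 - te) ** (pixel / width))


def fit_sre_band(
    points: list[TrappingPoint],
    pixel: float,
    candidates: list[float],
    min_coverage: float = 0.8,
) -> tuple[float, float]:
    """Pick the (low, high) candidate SRE pair that frames literature points.

    Among all ordered candidate pairs whose two Te(width) curves bracket at
    least ``min_coverage`` of the points, the pair with the smallest total
    squared distance from each point to its nearer curve wins.  If no pair
    brackets enough points, the widest candidate pair is returned with a
    warning.
    """
    if len(points) < 3:
        raise ValueError(f"need at least 3 trapping points, got {len(points)}")
    cands = sorted(set(candidates))
    widths = np.array([p.width for p in points])
    tes = np.array([p.te for p in points])

    def curve(sre: float) -> np.ndarray:
        return 1.0 - (1.0 - sre) ** (widths / pixel)

    best: tuple[float, float] | None = None
    best_sse = np.inf
    for i, lo in enumerate(cands):
        for hi in cands[i:]:
            te_lo, te_hi = curve(lo), curve(hi)
            inside = (tes >= te_lo - 1e-12) & (tes <= te_hi + 1e-12)
            if inside.mean() < min_coverage:
                continue
            sse = float(np.minimum((tes - te_lo) ** 2, (tes - te_hi) ** 2).sum())
            if sse < best_sse:
                best_sse, best = sse, (lo, hi)
    if best is None:
        warnings.warn(
            "no candidate SRE pair brackets enough trapping points; "
            "returning the widest pair"
        )
        return cands[0], cands[-1]
    return best


def load_literature_points() -> list[TrappingPoint]:
    """Editable packaged table of literature width-trapping observations."""
    with resources.files("sedscape.data").joinpath("trapping_points.csv").open() as fh:
        df = pd.read_csv(fh)
    return [
        TrappingPoint(float(r.width_m), float(r.te), str(r.source))
        for r in df.itertuples()
    ]
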