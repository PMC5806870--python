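"""Gridded-data carrier and plain-text raster I/O.

All gridded quantities (elevation, slope, LS, erodibility, cover factors,
soil loss, sediment maps) travel through :class:`Raster`: a row-major 2-D
float array with a cell size in metres, a nodata mask, and a local top-left
origin.  Files are read and written as ESRI ASCII grids, which keeps every
artefact human-readable and diffable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Raster", "read_ascii_grid", "write_ascii_grid"]

_NODATA = -9999.0


@dataclass
class Raster:
    """A rectangular grid of cell-centre values.

    Parameters
    ----------
    values
        2-D float array, row-major, row 0 at the top.
    cell_size
        Edge length of a square cell, metres. Must be positive.
    nodata_mask
        Boolean array, ``True`` where the cell carries no data. Defaults to
        all-valid.
    origin
        ``(x, y)`` of the top-left cell centre in an arbitrary local metric
        frame.
    """

    values: np.ndarray
    cell_size: float
    nodata_mask: np.ndarray | None = None
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"raster values must be 2-D, got {self.values.ndim}-D")
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.values.shape:
                raise ValueError(
                    f"nodata mask shape {self.nodata_mask.shape} does not match "
                    f"values shape {self.values.shape}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_valid(self) -> int:
        """Number of non-nodata cells."""
        return int((~self.nodata_mask).sum())

    @property
    def cell_area_ha(self) -> float:
        """Area of one cell in hectares."""
        return self.cell_size**2 / 1e4

    @property
    def valid_area_ha(self) -> float:
        """Total non-nodata area in hectares."""
        return self.n_valid * self.cell_area_ha

    def like(self, values: np.ndarray) -> "Raster":
        """A new raster sharing this one's geometry and mask."""
        return Raster(
            np.asarray(values, dtype=float),
            self.cell_size,
            self.nodata_mask.copy(),
            self.origin,
        )

    def copy(self) -> "Raster":
        return Raster(
            self.values.copy(), self.cell_size, self.nodata_mask.copy(), self.origin
        )

    def cell_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of every cell centre, metres."""
        ny, nx = self.shape
        x0, y0 = self.origin
        xs = x0 + np.arange(nx) * self.cell_size
        ys = y0 - np.arange(ny) * self.cell_size
        return np.meshgrid(xs, ys)

    def assert_aligned(self, other: "Raster", what: str = "raster") -> None:
        if self.shape != other.shape:
            raise ValueError(
                f"misaligned {what}: shape {other.shape} != {self.shape}"
            )
        if not np.isclose(self.cell_size, other.cell_size):
            raise ValueError(
                f"misaligned {what}: cell size {other.cell_size} != {self.cell_size}"
            )


def write_ascii_grid(raster: Raster, path: str | Path) -> None:
    """Write a raster as an ESRI ASCII grid (``.asc``)."""
    path = Path(path)
    ny, nx = raster.shape
    x0, y0 = raster.origin
    # ESRI convention: corner of the lower-left cell.
    xll = x0 - raster.cell_size / 2
    yll = y0 - (ny - 1) * raster.cell_size - raster.cell_size / 2
    vals = np.where(raster.nodata_mask, _NODATA, raster.values)
    header = (
        f"ncols {nx}\n"
        f"nrows {ny}\n"
        f"xllcorner {xll:.6f}\n"
        f"yllcorner {yll:.6f}\n"
        f"cellsize {raster.cell_size:.6f}\n"
        f"NODATA_value {_NODATA:g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.8g")


def read_ascii_grid(path: str | Path) -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid` or a GIS."""
    path = Path(path)
    header: dict[str, float] = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
                n_header += 1
            else:
                break
    values = np.loadtxt(path, skiprows=n_header, ndmin=2)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if values.shape != (nrows, ncols):
        raise ValueError(
            f"grid body {values.shape} does not match header ({nrows}, {ncols})"
        )
    cell = header["cellsize"]
    nodata = header.get("nodata_value", _NODATA)
    mask = values == nodata
    x0 = header["xllcorner"] + cell / 2
    y0 = header["yllcorner"] + (nrows - 1) * cell + cell / 2
    return Raster(values, cell, mask, (x0, y0))
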