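"""DEM conditioning and terrain derivatives.

Depression filling (priority flood), single-direction (D8) steepest-descent
flow routing with flow accumulation and stream extraction, percent slope by
Horn's stencil, the two-dimensional slope-length/steepness (LS) factor from
contributing area, and Euclidean distance to the stream network.

Conventions
-----------
Grids are row-major with row 0 at the top.  The eight neighbours are
scanned in the fixed order E, SE, S, SW, W, NW, N, NE; ties in steepest
descent resolve to the first of that order.  Flow accumulation counts
strictly upstream cells (the cell itself is excluded).  A cell whose
steepest descent leaves the grid (or enters nodata) is an outlet.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .raster import Raster

__all__ = [
    "FlowField",
    "SlopeLs",
    "fill_depressions",
    "d8_flow",
    "slope_percent",
    "ls_factor",
    "distance_to_stream",
]

# Neighbour offsets (drow, dcol) in tie-break order: E, SE, S, SW, W, NW, N, NE.
D8_OFFSETS: tuple[tuple[int, int], ...] = (
    (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1),
)
_DIAG = np.array([np.hypot(dr, dc) for dr, dc in D8_OFFSETS])

OUTLET = -1   # direction sentinel: flow exits the grid here
NODATA_DIR = -2


@dataclass
class FlowField:
    """D8 flow directions plus derived accumulation and stream mask.

    ``direction`` holds a neighbour index (0-7, order E..NE), ``OUTLET``
    where flow exits, or ``NODATA_DIR``.  ``downstream`` is the flat index
    of each cell's receiver (-1 at outlets/nodata).  ``topo_order`` lists
    flat cell indices upstream-first, so a single forward pass can route
    any quantity downslope.
    """

    direction: np.ndarray
    accumulation: np.ndarray
    streams: np.ndarray
    downstream: np.ndarray
    topo_order: np.ndarray
    threshold: int
    cell_size: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.direction.shape

    @property
    def n_valid(self) -> int:
        return int((self.direction != NODATA_DIR).sum())


@dataclass
class SlopeLs:
    slope_percent: Raster
    ls: Raster


def fill_depressions(dem: Raster) -> Raster:
    """Raise interior depressions to their spill elevation (priority flood).

    Cells already draining to the grid boundary are untouched; pit cells are
    raised exactly to the lowest elevation along their spill path.  Flats
    created (or preserved) by filling are resolved later by
    :func:`d8_flow`.
    """
    valid = ~dem.nodata_mask
    if not valid.any():
        raise ValueError("cannot fill an all-nodata DEM")
    ny, nx = dem.shape
    z = dem.values.copy()
    filled = np.full((ny, nx), np.inf)
    closed = np.zeros((ny, nx), dtype=bool)
    closed[~valid] = True

    heap: list[tuple[float, int, int]] = []
    # Seed with every valid cell on the grid edge or touching nodata.
    edge = valid & _boundary_mask(valid)
    for r, c in zip(*np.nonzero(edge)):
        filled[r, c] = z[r, c]
        heapq.heappush(heap, (z[r, c], int(r), int(c)))
    while heap:
        zc, r, c = heapq.heappop(heap)
        if closed[r, c]:
            continue
        closed[r, c] = True
        for dr, dc in D8_OFFSETS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < ny and 0 <= cc < nx and not closed[rr, cc]:
                fill_z = max(z[rr, cc], zc)
                if fill_z < filled[rr, cc]:
                    filled[rr, cc] = fill_z
                    heapq.heappush(heap, (fill_z, rr, cc))
    filled[~valid] = z[~valid]
    return dem.like(filled)


def _boundary_mask(valid: np.ndarray) -> np.ndarray:
    """Cells on the array edge or 8-adjacent to a nodata cell."""
    ny, nx = valid.shape
    b = np.zeros_like(valid)
    b[0, :] = b[-1, :] = b[:, 0] = b[:, -1] = True
    if (~valid).any():
        near_nodata = ndimage.binary_dilation(
            ~valid, structure=np.ones((3, 3), dtype=bool)
        )
        b |= near_nodata
    return b


def d8_flow(dem: Raster, threshold: int = 2000) -> FlowField:
    """Steepest-descent flow field of a depression-filled DEM.

    Flats remaining after filling are drained by a breadth-first sweep from
    cells that already have somewhere to go, pointing each flat cell at an
    equal-elevation resolved neighbour (flow moves away from higher terrain
    toward the flat's exits).  Streams are cells whose strictly-upstream
    accumulation count reaches ``threshold``.
    """
    valid = ~dem.nodata_mask
    if not valid.any():
        raise ValueError("cannot route an all-nodata DEM")
    ny, nx = dem.shape
    z = dem.values
    direction = np.full((ny, nx), NODATA_DIR, dtype=np.int8)

    boundary = _boundary_mask(valid)
    # Gradient to each neighbour, -inf off-grid/into-nodata; argmax over the
    # neighbour axis honours the E..NE tie-break order.
    grads = np.full((8, ny, nx), -np.inf)
    for k, (dr, dc) in enumerate(D8_OFFSETS):
        src = (slice(max(-dr, 0), ny - max(dr, 0)),
               slice(max(-dc, 0), nx - max(dc, 0)))
        dst = (slice(max(dr, 0), ny + min(dr, 0)),
               slice(max(dc, 0), nx + min(dc, 0)))
        g = (z[src] - z[dst]) / _DIAG[k]
        g[~valid[dst]] = -np.inf
        grads[k][src] = g
    best_k = grads.argmax(axis=0)
    best_grad = np.take_along_axis(grads, best_k[None], axis=0)[0]
    has_down = valid & (best_grad > 0)
    direction[has_down] = best_k[has_down]
    direction[valid & ~has_down & boundary] = OUTLET
    unresolved = [
        (int(r), int(c))
        for r, c in zip(*np.nonzero(valid & ~has_down & ~boundary))
    ]

    if unresolved:
        _drain_flats(direction, z, valid, unresolved)

    downstream = _downstream_index(direction)
    topo_order = _topological_order(direction, downstream)
    accumulation = _accumulate(direction, downstream, topo_order)
    streams = (accumulation >= threshold) & valid
    return FlowField(
        direction=direction,
        accumulation=accumulation,
        streams=streams,
        downstream=downstream,
        topo_order=topo_order,
        threshold=threshold,
        cell_size=dem.cell_size,
    )


def _drain_flats(
    direction: np.ndarray,
    z: np.ndarray,
    valid: np.ndarray,
    unresolved: list[tuple[int, int]],
) -> None:
    """BFS flat resolution: point flat cells at resolved equal-height cells."""
    ny, nx = z.shape
    pending = set(unresolved)
    # Seeds: resolved cells adjacent to a pending flat cell at equal height.
    queue: list[tuple[int, int]] = []
    for r, c in unresolved:
        for k, (dr, dc) in enumerate(D8_OFFSETS):
            rr, cc = r + dr, c + dc
            if (0 <= rr < ny and 0 <= cc < nx and valid[rr, cc]
                    and (rr, cc) not in pending
                    and direction[rr, cc] != NODATA_DIR
                    and z[rr, cc] <= z[r, c]):
                queue.append((rr, cc))
                break
    head = 0
    seen = set(queue)
    while head < len(queue):
        r, c = queue[head]
        head += 1
        for k, (dr, dc) in enumerate(D8_OFFSETS):
            rr, cc = r + dr, c + dc
            if (0 <= rr < ny and 0 <= cc < nx and (rr, cc) in pending
                    and z[rr, cc] == z[r, c]):
                # Point the flat cell back toward the resolved front.
                direction[rr, cc] = _reverse_direction(k)
                pending.discard((rr, cc))
                if (rr, cc) not in seen:
                    seen.add((rr, cc))
                    queue.append((rr, cc))
    if pending:
        cells = sorted(pending)[:20]
        raise ValueError(
            f"{len(pending)} unresolvable flat cell(s) after filling, "
            f"first few (row, col): {cells}"
        )


def _reverse_direction(k: int) -> int:
    return (k + 4) % 8


def _downstream_index(direction: np.ndarray) -> np.ndarray:
    """Flat receiver index per cell; -1 for outlets and nodata."""
    ny, nx = direction.shape
    down = np.full(ny * nx, -1, dtype=np.int64)
    rows, cols = np.nonzero(direction >= 0)
    ks = direction[rows, cols]
    offs = np.array(D8_OFFSETS)
    rr = rows + offs[ks, 0]
    cc = cols + offs[ks, 1]
    down[rows * nx + cols] = rr * nx + cc
    return down


def _topological_order(direction: np.ndarray, downstream: np.ndarray) -> np.ndarray:
    """Flat indices upstream-first (Kahn's algorithm); raises on cycles."""
    n = direction.size
    flat_valid = direction.ravel() != NODATA_DIR
    indeg = np.zeros(n, dtype=np.int64)
    targets = downstream[flat_valid & (downstream >= 0)]
    np.add.at(indeg, targets, 1)
    order = np.empty(int(flat_valid.sum()), dtype=np.int64)
    queue = list(np.nonzero(flat_valid & (indeg == 0))[0])
    pos = 0
    while queue:
        i = queue.pop()
        order[pos] = i
        pos += 1
        j = downstream[i]
        if j >= 0:
            indeg[j] -= 1
            if indeg[j] == 0:
                queue.append(j)
    if pos != order.size:
        raise ValueError("flow field contains a cycle")
    return order


def _accumulate(
    direction: np.ndarray, downstream: np.ndarray, topo_order: np.ndarray
) -> np.ndarray:
    acc = np.zeros(direction.size, dtype=np.int64)
    for i in topo_order:
        j = downstream[i]
        if j >= 0:
            acc[j] += acc[i] + 1
    return acc.reshape(direction.shape)


def slope_percent(dem: Raster) -> Raster:
    """Percent slope (100·rise/run) by Horn's 8-neighbour stencil.

    The DEM is padded by linear extrapolation so edge cells effectively use
    one-sided differences (a tilted plane gets its exact slope everywhere).
    """
    z = dem.values
    zp = np.pad(z, 1, mode="reflect", reflect_type="odd")
    dzdx = (
        (zp[:-2, 2:] + 2 * zp[1:-1, 2:] + zp[2:, 2:])
        - (zp[:-2, :-2] + 2 * zp[1:-1, :-2] + zp[2:, :-2])
    ) / (8 * dem.cell_size)
    dzdy = (
        (zp[2:, :-2] + 2 * zp[2:, 1:-1] + zp[2:, 2:])
        - (zp[:-2, :-2] + 2 * zp[:-2, 1:-1] + zp[:-2, 2:])
    ) / (8 * dem.cell_size)
    slope = 100.0 * np.hypot(dzdx, dzdy)
    slope[dem.nodata_mask] = 0.0
    return dem.like(slope)


def ls_factor(
    flow: FlowField,
    slope: Raster,
    cell_size: float | None = None,
    max_slope_length: float = 122.0,
) -> Raster:
    """Slope length-gradient factor from contributing area (Desmet-Govers).

    The length component uses the unit-contributing-area form

        L = ((A + D^2)^(m+1) - A^(m+1)) / (D^(m+2) * x^m * 22.13^m)

    with ``A`` the upstream contributing area at the cell inlet (m^2),
    ``D`` the cell size, ``x`` the aspect correction (1 for cardinal flow,
    sqrt(2) for diagonal), and a slope-dependent exponent
    ``m = beta / (1 + beta)``, ``beta = (sin t/0.0896)/(3 sin t^0.8 + 0.56)``.
    Steepness uses the McCool piecewise form: ``S = 10.8 sin t + 0.03`` below
    9% slope, ``S = 16.8 sin t - 0.50`` above.  The contributing area is
    capped so the effective slope length never exceeds ``max_slope_length``
    metres (the usual guard against unbounded lengths along convergent
    flowpaths); pass ``inf`` to disable.
    """
    if cell_size is None:
        cell_size = flow.cell_size
    if flow.shape != slope.shape:
        raise ValueError(
            f"flow field shape {flow.shape} does not match slope {slope.shape}"
        )
    if (flow.accumulation < 0).any():
        raise ValueError("negative flow accumulation")
    d = float(cell_size)
    area_in = flow.accumulation.astype(float) * d * d
    if np.isfinite(max_slope_length):
        area_in = np.minimum(area_in, d * max(max_slope_length - d, 0.0))

    theta = np.arctan(slope.values / 100.0)
    sin_t = np.sin(theta)
    beta = (sin_t / 0.0896) / (3.0 * sin_t**0.8 + 0.56)
    m = beta / (1.0 + beta)

    # Aspect correction from the flow direction: diagonals travel sqrt(2) D.
    x = np.ones(flow.shape)
    diag = np.isin(flow.direction, (1, 3, 5, 7))
    x[diag] = np.sqrt(2.0)

    L = ((area_in + d * d) ** (m + 1.0) - area_in ** (m + 1.0)) / (
        d ** (m + 2.0) * x**m * 22.13**m
    )
    S = np.where(slope.values < 9.0, 10.8 * sin_t + 0.03, 16.8 * sin_t - 0.50)
    ls = L * S
    ls[flow.direction == NODATA_DIR] = 0.0
    return Raster(ls, d, slope.nodata_mask.copy(), slope.origin)


def distance_to_stream(streams: np.ndarray, cell_size: float) -> Raster:
    """Euclidean distance (m) from each cell centre to the nearest stream cell."""
    streams = np.asarray(streams, dtype=bool)
    if not streams.any():
        raise ValueError("stream mask is empty")
    dist = ndimage.distance_transform_edt(~streams, sampling=cell_size)
    return Raster(dist, cell_size)
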