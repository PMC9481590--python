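"""Least-cost travel time to the nearest health facility.

The friction grid induces a weighted graph on its non-barrier cells: each
cell connects to its eight neighbours, and the cost of stepping between
adjacent cells a and b is the mean of their crossing times, (t_a + t_b)/2,
scaled by sqrt(2) for diagonal steps — the standard cost-surface transition
used by the r.cost/AccessMod family.  Travel time is the exact multi-source
shortest-path distance from the facility seed cells, computed with a priority
-queue Dijkstra (scipy's compiled implementation), so results are
deterministic and checkable against a brute-force oracle.  Movement is
isotropic: no slope or direction corrections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .friction import FrictionGrid
from .grid import GridSpec
from .vectors import FeatureCollection

__all__ = ["FacilitySeedSet", "TravelTimeGrid", "seed_facilities", "least_cost_travel_time",
           "NoFacilityError", "UNREACHABLE"]

log = logging.getLogger(__name__)

#: Sentinel written to travel-time rasters for land cells with no path to any
#: facility; barrier cells use the raster nodata marker instead.
UNREACHABLE = -1.0

SQRT2 = float(np.sqrt(2.0))


class NoFacilityError(ValueError):
    """No facility could be seeded onto the friction grid."""


@dataclass
class FacilitySeedSet:
    """Facilities mapped onto non-barrier host cells."""

    cells: list[tuple[int, int]]
    displacements_cells: list[float] = field(default_factory=list)
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.cells)


@dataclass
class TravelTimeGrid:
    """Minutes to the nearest facility; NaN on barriers, inf where unreachable."""

    minutes: np.ndarray
    barrier_mask: np.ndarray
    grid: GridSpec

    @property
    def unreachable_mask(self) -> np.ndarray:
        return np.isinf(self.minutes) & ~self.barrier_mask


def _snap_offsets(radius: int) -> list[tuple[float, int, int]]:
    """Candidate cell offsets within ``radius``, ordered by (distance, row, col).

    Row-major order breaks Euclidean ties deterministically.
    """
    offs = []
    for dr in range(-radius, radius + 1):
        for dc in range(-radius, radius + 1):
            d = float(np.hypot(dr, dc))
            if d <= radius:
                offs.append((d, dr, dc))
    offs.sort()
    return offs


def seed_facilities(
    facilities: FeatureCollection,
    friction: FrictionGrid,
    snap_radius_cells: int = 5,
) -> FacilitySeedSet:
    """Overlay facility points on the friction grid.

    Each facility maps to its containing cell (half-open extents).  A facility
    whose cell is a barrier is snapped to the nearest non-barrier cell within
    the radius (Euclidean cell distance, ties broken row-major); facilities
    that cannot be snapped, or fall outside the grid, are dropped and logged.
    """
    if snap_radius_cells < 0:
        raise ValueError("snap_radius_cells must be >= 0")
    grid = friction.grid
    grid.require_crs(facilities.crs_id)
    offsets = _snap_offsets(snap_radius_cells)
    cells: list[tuple[int, int]] = []
    displacements: list[float] = []
    dropped = 0
    for feat in facilities:
        pt = feat.geometry
        if pt.geom_type != "Point":
            pt = shapely.centroid(pt)
        row, col = grid.cell_of(pt.x, pt.y)
        row, col = int(row), int(col)
        if row < 0 or col < 0:
            dropped += 1
            continue
        placed = False
        for d, dr, dc in offsets:
            r, c = row + dr, col + dc
            if 0 <= r < grid.n_rows and 0 <= c < grid.n_cols and not friction.barrier_mask[r, c]:
                cells.append((r, c))
                displacements.append(d)
                if d > 0:
                    log.info("facility snapped %.2f cells from (%d,%d) to (%d,%d)",
                             d, row, col, r, c)
                placed = True
                break
        if not placed:
            dropped += 1
    if dropped:
        log.warning("%d facilities dropped (outside grid or unsnappable within %d cells)",
                    dropped, snap_radius_cells)
    if not cells:
        raise NoFacilityError("no facility could be seeded onto a non-barrier cell")
    return FacilitySeedSet(cells=cells, displacements_cells=displacements, n_dropped=dropped)


def _lattice_graph(friction: FrictionGrid) -> coo_matrix:
    """Sparse symmetric edge matrix of the 8-connected non-barrier lattice."""
    t = np.where(friction.barrier_mask, np.nan, friction.minutes)
    n_rows, n_cols = friction.grid.shape
    n = n_rows * n_cols
    rows_i, cols_i, weights = [], [], []
    # four unique neighbour directions; the other four are the symmetric pairs
    for dr, dc, diag in ((0, 1, False), (1, 0, False), (1, 1, True), (1, -1, True)):
        r0 = slice(max(0, -dr), n_rows - max(0, dr))
        c0 = slice(max(0, -dc), n_cols - max(0, dc))
        r1 = slice(max(0, dr), n_rows - max(0, -dr))
        c1 = slice(max(0, dc), n_cols - max(0, -dc))
        ta, tb = t[r0, c0], t[r1, c1]
        w = 0.5 * (ta + tb)
        if diag:
            w = w * SQRT2
        ok = np.isfinite(w)
        idx_a = (np.arange(n_rows)[r0][:, None] * n_cols + np.arange(n_cols)[c0][None, :])
        idx_b = (np.arange(n_rows)[r1][:, None] * n_cols + np.arange(n_cols)[c1][None, :])
        rows_i.append(idx_a[ok])
        cols_i.append(idx_b[ok])
        weights.append(w[ok])
    return coo_matrix(
        (np.concatenate(weights), (np.concatenate(rows_i), np.concatenate(cols_i))),
        shape=(n, n),
    )


def least_cost_travel_time(friction: FrictionGrid, seeds: FacilitySeedSet) -> TravelTimeGrid:
    """Exact eight-directional multi-source shortest-path travel time.

    Returns minutes to the nearest seed for every cell; ``inf`` for finite
    -friction cells no barrier-free 8-connected path reaches, NaN on barriers.
    """
    if len(seeds) == 0:
        raise NoFacilityError("at least one seeded facility is required")
    grid = friction.grid
    graph = _lattice_graph(friction)
    seed_idx = np.unique([r * grid.n_cols + c for r, c in seeds.cells])
    dist = dijkstra(graph.tocsr(), directed=False, indices=seed_idx, min_only=True)
    minutes = dist.reshape(grid.shape)
    minutes = np.where(friction.barrier_mask, np.nan, minutes)
    return TravelTimeGrid(minutes=minutes, barrier_mask=friction.barrier_mask.copy(), grid=grid)
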