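"""Georeferenced lattice geometry shared by every raster in an analysis.

All grids in one run live on a single projected, metric coordinate reference
system.  Cell (0, 0) sits at the north-west corner; the centroid of cell
(row, col) is ``origin + ((col + 0.5) * cell_size, -(row + 0.5) * cell_size)``.
Point-in-cell tests are half-open: a point on the northern or western edge of
a cell belongs to that cell, a point on the southern or eastern edge belongs
to the neighbour.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import shapely

__all__ = ["GridSpec", "CRSMismatchError"]

# Identifiers of well-known geographic (lat/lon) systems; a metric, projected
# CRS is required because friction is expressed in minutes per metre crossed.
_GEOGRAPHIC_IDS = {"epsg:4326", "epsg:4269", "wgs84", "crs84", "ogc:crs84"}


class CRSMismatchError(ValueError):
    """Layers on different coordinate reference systems were combined."""


@dataclass(frozen=True)
class GridSpec:
    """Shape, placement and CRS of a raster lattice with square cells.

    Parameters
    ----------
    n_rows, n_cols
        Lattice dimensions, at least 1 each.
    origin_x, origin_y
        Map coordinates (metres) of the north-west corner of cell (0, 0).
    cell_size
        Edge length of a cell in metres (100 m in the reference analysis).
    crs_id
        Identifier of a projected, metric CRS.  Geographic identifiers
        (EPSG:4326 and friends) are rejected.
    """

    n_rows: int
    n_cols: int
    origin_x: float
    origin_y: float
    cell_size: float
    crs_id: str = "local:metric"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        if self.crs_id.strip().lower() in _GEOGRAPHIC_IDS:
            raise ValueError(
                f"crs_id {self.crs_id!r} names a geographic system; "
                "a projected metric CRS is required"
            )

    # -- extents ----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(min_x, min_y, max_x, max_y) of the full lattice."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.cell_size,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y,
        )

    # -- point <-> cell ---------------------------------------------------

    def cell_of(self, x, y):
        """Map point coordinates to (row, col) arrays; -1 where outside.

        Half-open convention: ``col = floor((x - origin_x) / cell_size)`` and
        ``row = floor((origin_y - y) / cell_size)``, except that points on the
        southern/eastern outer boundary of the lattice are counted into the
        last row/column so the domain itself is closed.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        fc = (x - self.origin_x) / self.cell_size
        fr = (self.origin_y - y) / self.cell_size
        col = np.floor(fc).astype(np.int64)
        row = np.floor(fr).astype(np.int64)
        # close the outer south/east boundary
        col = np.where((fc == self.n_cols) & (col == self.n_cols), self.n_cols - 1, col)
        row = np.where((fr == self.n_rows) & (row == self.n_rows), self.n_rows - 1, row)
        inside = (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)
        return np.where(inside, row, -1), np.where(inside, col, -1)

    def cell_centroid(self, row, col):
        """Centroid map coordinates of cell (row, col)."""
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.origin_x + (col + 0.5) * self.cell_size
        y = self.origin_y - (row + 0.5) * self.cell_size
        return x, y

    def centroids(self):
        """(x, y) coordinate arrays of shape (n_rows, n_cols)."""
        rows, cols = np.meshgrid(
            np.arange(self.n_rows), np.arange(self.n_cols), indexing="ij"
        )
        return self.cell_centroid(rows, cols)

    def cell_box(self, row: int, col: int) -> shapely.Geometry:
        """Shapely box of the cell's extent."""
        x0 = self.origin_x + col * self.cell_size
        y1 = self.origin_y - row * self.cell_size
        return shapely.box(x0, y1 - self.cell_size, x0 + self.cell_size, y1)

    # -- relations --------------------------------------------------------

    def same_lattice(self, other: "GridSpec", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and abs(self.origin_x - other.origin_x) <= tol
            and abs(self.origin_y - other.origin_y) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
            and self.crs_id == other.crs_id
        )

    def require_crs(self, crs_id: str) -> None:
        if crs_id != self.crs_id:
            raise CRSMismatchError(
                f"layer CRS {crs_id!r} differs from grid CRS {self.crs_id!r}; "
                "reproject inputs before the analysis — nothing is resampled silently"
            )

    def coarsen(self, factor: int) -> "GridSpec":
        """Grid with ``factor``-times larger cells covering the same origin.

        The coarse lattice spans ceil(n/factor) blocks, so it may overhang the
        fine lattice on the south/east edge.
        """
        if factor < 1 or int(factor) != factor:
            raise ValueError("coarsening factor must be a positive integer")
        return replace(
            self,
            n_rows=-(-self.n_rows // factor),
            n_cols=-(-self.n_cols // factor),
            cell_size=self.cell_size * factor,
        )
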