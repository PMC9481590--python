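"""Raster reading and writing.

Rasters are exchanged as single-band ESRI ASCII Grid files (``.asc``): a
six-line header (ncols, nrows, xllcorner, yllcorner, cellsize, NODATA_value)
followed by whitespace-separated cell values in row-major order from the
north-west corner.  The format is plain text, diffable, and read natively by
GDAL, QGIS and ArcGIS.  Because ASCII Grid carries no CRS, a sidecar ``.prj``
file next to the raster stores the CRS identifier; a raster without one is
rejected rather than guessed at.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .grid import GridSpec

__all__ = ["Raster", "read_raster", "write_raster", "RasterFormatError", "RasterCRSError"]

log = logging.getLogger(__name__)

DEFAULT_NODATA = -9999.0

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


class RasterFormatError(ValueError):
    """The file is not a well-formed single-band ASCII Grid."""


class RasterCRSError(ValueError):
    """The raster's CRS sidecar is missing or unreadable."""


@dataclass
class Raster:
    """A single-band lattice of values with its grid and nodata marker."""

    values: np.ndarray
    grid: GridSpec
    nodata: float = DEFAULT_NODATA

    @property
    def nodata_mask(self) -> np.ndarray:
        return self.values == self.nodata

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise RasterFormatError(
                f"expected a single-band (2-D) lattice, got {self.values.ndim} dimensions"
            )
        if self.values.shape != self.grid.shape:
            raise RasterFormatError(
                f"lattice shape {self.values.shape} does not match grid {self.grid.shape}"
            )


def _prj_path(path: Path) -> Path:
    return path.with_suffix(".prj")


def read_raster(path) -> Raster:
    """Read an ASCII Grid raster and its CRS sidecar.

    Returns the value lattice untouched (no resampling, nodata cells keep the
    marker value), the :class:`GridSpec`, and the nodata marker bundled in a
    :class:`Raster`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raster not found: {path}")

    header: dict[str, float] = {}
    nodata = DEFAULT_NODATA
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS + ("nodata_value",):
                key = parts[0].lower()
                if key == "nodata_value":
                    nodata = float(parts[1])
                else:
                    header[key] = float(parts[1])
                pos = fh.tell()
            else:
                break
        missing = [k for k in _HEADER_KEYS if k not in header]
        if missing:
            raise RasterFormatError(f"{path}: ASCII Grid header lacks {missing}")
        fh.seek(pos)
        values = np.loadtxt(fh, ndmin=2)

    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (n_rows, n_cols):
        raise RasterFormatError(
            f"{path}: data block is {values.shape}, header says ({n_rows}, {n_cols}); "
            "multi-band or truncated input is not supported"
        )

    prj = _prj_path(path)
    if not prj.exists():
        raise RasterCRSError(f"{path}: CRS sidecar {prj.name} is missing")
    crs_id = prj.read_text().strip()
    if not crs_id:
        raise RasterCRSError(f"{path}: CRS sidecar {prj.name} is empty")

    cell = header["cellsize"]
    grid = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + n_rows * cell,
        cell_size=cell,
        crs_id=crs_id,
    )
    return Raster(values=values, grid=grid, nodata=nodata)


def write_raster(path, values: np.ndarray, grid: GridSpec, nodata: float = DEFAULT_NODATA) -> Path:
    """Write a lattice as ASCII Grid plus a ``.prj`` CRS sidecar.

    NaN cells are serialized as the nodata marker.  Values round-trip through
    ``%.10g`` formatting, which preserves float32-level precision.
    """
    path = Path(path)
    values = np.asarray(values)
    if values.shape != grid.shape:
        raise RasterFormatError(
            f"lattice shape {values.shape} does not match grid {grid.shape}"
        )
    out = np.where(np.isnan(values.astype(float)), nodata, values)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.origin_x:.6f}\n")
        fh.write(f"yllcorner {grid.origin_y - grid.n_rows * grid.cell_size:.6f}\n")
        fh.write(f"cellsize {grid.cell_size:.6f}\n")
        fh.write(f"NODATA_value {nodata:.10g}\n")
        np.savetxt(fh, out, fmt="%.10g")
    _prj_path(path).write_text(grid.crs_id + "\n")
    return path
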