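"""Population grid harmonization and centroid-point extraction.

Gridded population products arrive at heterogeneous resolutions.  To avoid
resampling them, each product is (1) harmonized — clipped to the study region
with per-unit mass restored by multiplicative rescaling at administrative
level 2 — and then (2) converted to centroid points carrying the cell count,
which are classified against the travel-time surface and administrative
polygons by direct lookup.  Total population is preserved end to end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.strtree import STRtree

from .grid import GridSpec, CRSMismatchError
from .travel import TravelTimeGrid
from .vectors import FeatureCollection

__all__ = [
    "PopulationGrid",
    "HarmonizeReport",
    "harmonize",
    "to_points",
    "classify_points",
    "STATUS_OK",
    "STATUS_BARRIER",
    "STATUS_UNREACHABLE",
    "STATUS_OUT_OF_REGION",
]

log = logging.getLogger(__name__)

STATUS_OK = "ok"
STATUS_BARRIER = "barrier"
STATUS_UNREACHABLE = "unreachable"
STATUS_OUT_OF_REGION = "out_of_region"


@dataclass
class PopulationGrid:
    """Nonnegative person counts on a grid; NaN marks nodata."""

    values: np.ndarray
    grid: GridSpec
    name: str

    def __post_init__(self) -> None:
        if self.values.shape != self.grid.shape:
            raise ValueError("population lattice does not match its grid")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and finite.min() < 0:
            raise ValueError(f"dataset {self.name!r} contains negative counts")

    @property
    def total(self) -> float:
        return float(np.nansum(self.values))


@dataclass
class HarmonizeReport:
    """Per-unit rescale factors and fallback actions taken."""

    factors: dict[str, float] = field(default_factory=dict)
    respread_units: list[str] = field(default_factory=list)
    dropped_mass: float = 0.0


def _unit_index(features: FeatureCollection, id_attr: str):
    """STRtree plus stable-id-ordered feature list for point assignment."""
    feats = sorted(features, key=lambda f: str(f.attrs[id_attr]))
    tree = STRtree([f.geometry for f in feats])
    ids = [str(f.attrs[id_attr]) for f in feats]
    return tree, feats, ids


def assign_units(x: np.ndarray, y: np.ndarray, features: FeatureCollection,
                 id_attr: str = "admin_id") -> np.ndarray:
    """Unit id per point, or '' outside all polygons.

    A point on a shared boundary is assigned to the first covering polygon in
    stable id order, so assignment is deterministic and single-valued.
    """
    tree, feats, ids = _unit_index(features, id_attr)
    pts = shapely.points(np.asarray(x, float), np.asarray(y, float))
    out = np.full(len(pts), "", dtype=object)
    pt_idx, geom_idx = tree.query(pts, predicate="intersects")
    if len(pt_idx):
        order = np.lexsort((geom_idx, pt_idx))  # first covering polygon in id order
        pt_idx, geom_idx = pt_idx[order], geom_idx[order]
        first = np.unique(pt_idx, return_index=True)[1]
        out[pt_idx[first]] = [ids[g] for g in geom_idx[first]]
    return out.astype(str)


def harmonize(
    raw: PopulationGrid,
    level2_units: FeatureCollection,
    target_crs: str | None = None,
    original_totals: dict[str, float] | None = None,
    id_attr: str = "admin_id",
    land_mask: np.ndarray | None = None,
) -> tuple[PopulationGrid, HarmonizeReport]:
    """Clip to the level-2 region and restore per-unit population mass.

    Cells whose centroid falls outside every level-2 unit are set to nodata.
    Then, per unit, counts are multiplied by ``original_total / clipped_total``
    so the unit's mass matches the original product exactly; the rescaling is
    proportional, preserving the within-unit spatial pattern (an additive
    spread would fill the deliberate zero cells of settlement-constrained
    products).  A unit whose clipped total is 0 but whose original total is
    positive gets the original total spread uniformly over its (land) cells,
    with a warning.

    ``original_totals`` gives each unit's total in the original product when
    the raw raster has already lost mass upstream; by default the raw raster
    itself is the original.  All layers must share one CRS: there is no
    reprojection path, mixed-CRS inputs are refused.
    """
    grid = raw.grid
    grid.require_crs(level2_units.crs_id)
    if target_crs is not None and target_crs != grid.crs_id:
        raise CRSMismatchError(
            f"target CRS {target_crs!r} differs from raster CRS {grid.crs_id!r}; "
            "single-CRS runs only"
        )
    x, y = grid.centroids()
    unit_of_cell = assign_units(x.ravel(), y.ravel(), level2_units, id_attr).reshape(grid.shape)
    inside = unit_of_cell != ""
    if not inside.any():
        raise ValueError("level-2 region is disjoint from the population raster")

    values = np.where(np.isnan(raw.values), 0.0, raw.values)
    if original_totals is None:
        original_totals = {
            uid: float(values[unit_of_cell == uid].sum())
            for uid in np.unique(unit_of_cell[inside])
        }

    out = np.where(inside, values, np.nan)
    report = HarmonizeReport(dropped_mass=float(values[~inside].sum()))
    if land_mask is None:
        land_mask = np.ones(grid.shape, dtype=bool)
    for uid, orig in original_totals.items():
        sel = unit_of_cell == uid
        clipped = float(values[sel].sum())
        if clipped > 0:
            factor = orig / clipped
            out[sel] = values[sel] * factor
            report.factors[uid] = factor
        elif orig > 0:
            spread = sel & land_mask
            if not spread.any():
                spread = sel
            out[spread] = orig / spread.sum()
            report.respread_units.append(uid)
            log.warning(
                "unit %s lost all population in processing; %.1f persons respread "
                "uniformly over %d cells", uid, orig, int(spread.sum()),
            )
        else:
            report.factors[uid] = 1.0
    return PopulationGrid(values=out, grid=grid, name=raw.name), report


def to_points(pop: PopulationGrid) -> pd.DataFrame:
    """One point per positive-count cell, at the cell centroid.

    Columns: x, y, count, dataset.  Zero-count and nodata cells are omitted;
    the count total is preserved exactly.
    """
    values = pop.values
    rows, cols = np.nonzero(np.nan_to_num(values, nan=0.0) > 0)
    if rows.size == 0:
        log.warning("dataset %s: no positive population cells", pop.name)
    x, y = pop.grid.cell_centroid(rows, cols)
    return pd.DataFrame(
        {"x": x, "y": y, "count": values[rows, cols], "dataset": pop.name}
    )


def classify_points(
    points: pd.DataFrame,
    travel: TravelTimeGrid,
    admin: dict[int, FeatureCollection],
    levels: tuple[int, ...] = (1, 2),
    id_attr: str = "admin_id",
) -> pd.DataFrame:
    """Annotate points with travel time, status, and admin-unit ids.

    Each point takes the travel-time value of its containing cell and ends in
    exactly one status: ``ok`` (finite minutes), ``barrier``, ``unreachable``,
    or ``out_of_region`` (outside the grid, or outside every polygon of the
    finest requested admin level).
    """
    out = points.copy()
    grid = travel.grid
    x = out["x"].to_numpy(float)
    y = out["y"].to_numpy(float)
    row, col = grid.cell_of(x, y)
    inside = row >= 0
    minutes = np.full(len(out), np.nan)
    minutes[inside] = travel.minutes[row[inside], col[inside]]
    on_barrier = np.zeros(len(out), dtype=bool)
    on_barrier[inside] = travel.barrier_mask[row[inside], col[inside]]

    status = np.full(len(out), STATUS_OK, dtype=object)
    status[~inside] = STATUS_OUT_OF_REGION
    status[inside & on_barrier] = STATUS_BARRIER
    status[inside & ~on_barrier & np.isinf(minutes)] = STATUS_UNREACHABLE

    finest = max(lv for lv in levels if lv > 0) if any(lv > 0 for lv in levels) else None
    for level in sorted(lv for lv in levels if lv > 0):
        fc = admin[level]
        grid.require_crs(fc.crs_id)
        ids = assign_units(x, y, fc, id_attr)
        out[f"admin{level}_id"] = ids
        if level == finest:
            status[(ids == "") & (status != STATUS_OUT_OF_REGION)] = STATUS_OUT_OF_REGION

    out["travel_time_min"] = np.where(np.isfinite(minutes), minutes, np.nan)
    out["status"] = status.astype(str)
    return out
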