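"""Friction-surface construction.

The merged class grid stacks three layers with a fixed priority: roads beat
barriers (a road crossing water is a bridge or ford), barriers beat land
cover, and land cover fills everything else.  The friction surface then
converts each cell's class to the time, in minutes, needed to cross one cell
orthogonally at that class's scenario speed:

    crossing_minutes = (cell_size / 1000) / speed_kmh * 60

The surface is isotropic and direction-free; diagonal movement is handled
entirely by the travel-time stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import shapely

from .grid import GridSpec
from .scenario import ScenarioRow, ScenarioTable, ScenarioError
from .vectors import FeatureCollection

__all__ = [
    "MergedClassGrid",
    "FrictionGrid",
    "rasterize_lines",
    "rasterize_barriers",
    "merge_layers",
    "resolve_scenario",
    "build_friction",
    "PROV_LANDCOVER",
    "PROV_ROAD",
    "PROV_BARRIER",
    "NO_CLASS",
]

log = logging.getLogger(__name__)

PROV_LANDCOVER = 0
PROV_ROAD = 1
PROV_BARRIER = 2

NO_CLASS = -1  # sentinel for "no line rasterized here"


@dataclass
class MergedClassGrid:
    """One class code and one provenance tag per cell."""

    classes: np.ndarray  # int lattice
    provenance: np.ndarray  # int lattice of PROV_* tags
    grid: GridSpec
    barrier_class: int

    def __post_init__(self) -> None:
        if self.classes.shape != self.grid.shape or self.provenance.shape != self.grid.shape:
            raise ValueError("lattice shapes must match the grid")


@dataclass
class FrictionGrid:
    """Per-cell orthogonal crossing time in minutes; barrier cells are NaN."""

    minutes: np.ndarray  # float lattice, NaN on barriers
    barrier_mask: np.ndarray  # bool lattice
    grid: GridSpec

    def __post_init__(self) -> None:
        finite = self.minutes[~self.barrier_mask]
        if finite.size and not np.all(finite > 0):
            raise ValueError("friction crossing times must be positive")


def _window(grid: GridSpec, bounds: tuple[float, float, float, float]):
    """Row/col index ranges of grid cells whose boxes can touch ``bounds``."""
    minx, miny, maxx, maxy = bounds
    c0 = max(0, int(np.floor((minx - grid.origin_x) / grid.cell_size)))
    c1 = min(grid.n_cols - 1, int(np.floor((maxx - grid.origin_x) / grid.cell_size)))
    r0 = max(0, int(np.floor((grid.origin_y - maxy) / grid.cell_size)))
    r1 = min(grid.n_rows - 1, int(np.floor((grid.origin_y - miny) / grid.cell_size)))
    if c1 < c0 or r1 < r0:
        return None
    return r0, r1, c0, c1


def _cells_touching(geom: shapely.Geometry, grid: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """All-touched rasterization: (rows, cols) of every cell box the geometry intersects."""
    win = _window(grid, geom.bounds)
    if win is None:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    r0, r1, c0, c1 = win
    rows, cols = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    rows, cols = rows.ravel(), cols.ravel()
    x0 = grid.origin_x + cols * grid.cell_size
    y1 = grid.origin_y - rows * grid.cell_size
    boxes = shapely.box(x0, y1 - grid.cell_size, x0 + grid.cell_size, y1)
    hit = shapely.intersects(boxes, geom)
    return rows[hit], cols[hit]


def rasterize_lines(
    lines: FeatureCollection,
    grid: GridSpec,
    class_speed_kmh: Mapping[int, float],
    class_attr: str = "class_code",
) -> np.ndarray:
    """Rasterize classed polylines onto the grid, all-touched.

    Every cell whose box the line intersects receives the line's class code.
    Where lines of different classes touch the same cell the class with the
    higher scenario speed wins, which preserves connectivity of the faster
    road.  Cells no line touches hold :data:`NO_CLASS`.
    """
    grid.require_crs(lines.crs_id)
    out = np.full(grid.shape, NO_CLASS, dtype=np.int64)
    best = np.full(grid.shape, -np.inf)
    for feat in lines:
        code = int(feat.attrs[class_attr])
        try:
            speed = float(class_speed_kmh[code])
        except KeyError:
            raise ScenarioError(f"no speed known for line class {code}") from None
        rows, cols = _cells_touching(feat.geometry, grid)
        take = speed > best[rows, cols]
        out[rows[take], cols[take]] = code
        best[rows[take], cols[take]] = speed
    return out


def rasterize_barriers(
    river_lines: FeatureCollection | None,
    water_polygons: FeatureCollection | None,
    grid: GridSpec,
) -> np.ndarray:
    """Barrier mask: all-touched for river lines, centroid-coverage for polygons.

    Lines use the all-touched rule so a narrow river stays a continuous
    barrier at coarse resolution; polygons mark only cells whose centroid the
    polygon covers, so lake edges are not inflated.
    """
    mask = np.zeros(grid.shape, dtype=bool)
    if river_lines is not None and len(river_lines):
        grid.require_crs(river_lines.crs_id)
        for feat in river_lines:
            rows, cols = _cells_touching(feat.geometry, grid)
            mask[rows, cols] = True
    if water_polygons is not None and len(water_polygons):
        grid.require_crs(water_polygons.crs_id)
        union = shapely.union_all(water_polygons.geometries())
        win = _window(grid, union.bounds)
        if win is not None:
            r0, r1, c0, c1 = win
            rows, cols = np.meshgrid(
                np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij"
            )
            x, y = grid.cell_centroid(rows.ravel(), cols.ravel())
            covered = shapely.intersects(shapely.points(x, y), union)
            mask[rows.ravel()[covered], cols.ravel()[covered]] = True
    return mask


def merge_layers(
    landcover: np.ndarray,
    road_classes: np.ndarray,
    barrier_mask: np.ndarray,
    grid: GridSpec,
    barrier_class: int,
) -> MergedClassGrid:
    """Merge land cover, rasterized roads and barriers with road > barrier > landcover.

    Road cells keep their road class even over water (the bridge rule);
    remaining barrier cells become ``barrier_class``; everything else keeps
    its land-cover class.  Land cover must be complete.
    """
    landcover = np.asarray(landcover)
    if landcover.shape != grid.shape:
        raise ValueError("landcover lattice does not match the grid")
    if np.any(landcover < 0):
        bad = int(np.sum(landcover < 0))
        raise ValueError(f"landcover layer is incomplete: {bad} cells carry no class")
    classes = landcover.astype(np.int64).copy()
    provenance = np.full(grid.shape, PROV_LANDCOVER, dtype=np.int8)

    barrier_only = barrier_mask & (road_classes == NO_CLASS)
    classes[barrier_only] = barrier_class
    provenance[barrier_only] = PROV_BARRIER

    on_road = road_classes != NO_CLASS
    classes[on_road] = road_classes[on_road]
    provenance[on_road] = PROV_ROAD

    n_bridge = int(np.sum(barrier_mask & on_road))
    if n_bridge:
        log.info("bridge rule kept %d road cells that cross barriers", n_bridge)
    return MergedClassGrid(classes=classes, provenance=provenance, grid=grid,
                           barrier_class=barrier_class)


def resolve_scenario(
    scenario: ScenarioTable,
    classes_present: Sequence[int],
    fallback_kmh: Mapping[int, float] | None = None,
) -> ScenarioTable:
    """Complete the scenario for every class present in the merged grid.

    Classes missing from the scenario are filled from the fallback table of
    average road speeds (and logged); a class covered by neither is a hard
    error naming the class.
    """
    fallback_kmh = fallback_kmh or {}
    missing = [c for c in sorted(set(int(c) for c in classes_present)) if c not in scenario]
    extra = []
    unresolved = []
    for code in missing:
        if code in fallback_kmh:
            extra.append(
                ScenarioRow(code, f"class {code} (fallback average)", "road",
                            float(fallback_kmh[code]))
            )
            log.info("class %d missing from scenario; filled from fallback at %.1f km/h",
                     code, fallback_kmh[code])
        else:
            unresolved.append(code)
    if unresolved:
        raise ScenarioError(
            f"classes {unresolved} present in the merged grid have neither a scenario "
            "row nor a fallback speed"
        )
    return scenario.with_rows(extra) if extra else scenario


def build_friction(merged: MergedClassGrid, scenario: ScenarioTable) -> FrictionGrid:
    """Convert the merged class grid to per-cell crossing minutes."""
    grid = merged.grid
    barrier_codes = scenario.barrier_classes() | {merged.barrier_class}
    minutes = np.full(grid.shape, np.nan)
    barrier_mask = np.isin(merged.classes, sorted(barrier_codes))
    km_per_cell = grid.cell_size / 1000.0
    for code in np.unique(merged.classes[~barrier_mask]):
        t = km_per_cell / scenario.speed(int(code)) * 60.0
        if not t > 0:
            raise ValueError(f"non-positive crossing time for class {code}")
        minutes[merged.classes == code] = t
    return FrictionGrid(minutes=minutes, barrier_mask=barrier_mask, grid=grid)
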