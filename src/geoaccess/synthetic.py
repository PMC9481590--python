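"""Synthetic study regions with ground truth.

A world is a projected, metric lattice carrying: clustered settlements of
households (a parent–child / Thomas-style point process, so some admin units
end up dense and others sparse), a road network linking settlements (nearest
-neighbour links plus a spanning tree), meandering river barriers and lakes,
health facilities at a subset of settlement centres, and a nested two-level
administrative partition of randomly-sized rectangles.  Because household
locations are known exactly, coverage computed from any gridded population
product of the world can be judged against the truth.

Population rasters are derived from the same truth under three allocation
families that emulate how real gridded products disaggregate census totals:

* ``constrained`` — counts only on detected settlement footprint cells
  (whole settlements are missed with a configurable probability, emulating
  imperfect building detection), proportional to true household density;
* ``unconstrained_uniform`` — each census unit's total spread equally over
  every non-water cell of the unit;
* ``unconstrained_covariate`` — spread proportional to a Gaussian-smoothed
  settlement-proximity covariate perturbed by lognormal noise, an
  intermediate behaviour.

Every scheme redistributes strictly within census units, so per-unit totals
always equal the truth; the schemes differ only in where the mass lands.
All randomness flows from a single seed through named substreams, one per
generation stage, so stages are independently reproducible.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import cdist
from shapely.geometry import LineString, Point, box

from .friction import rasterize_barriers
from .grid import GridSpec
from .population import PopulationGrid, assign_units
from .scenario import (
    CLASS_FOREST,
    CLASS_OPEN,
    CLASS_ROAD_PRIMARY,
    CLASS_ROAD_SECONDARY,
    CLASS_SETTLEMENT,
    CLASS_WATER,
)
from .travel import TravelTimeGrid
from .vectors import Feature, FeatureCollection, write_vectors

__all__ = [
    "WorldConfig",
    "AllocationScheme",
    "Settlement",
    "SyntheticWorld",
    "TrueCoverage",
    "make_world",
    "allocate_population",
    "true_coverage",
    "default_schemes",
    "export_world",
]

log = logging.getLogger(__name__)

# Fixed order of the per-stage random substreams spawned from the world seed.
_STAGES = ("rivers", "lakes", "settlements", "households", "roads", "facilities",
           "admin", "landcover")


@dataclass
class WorldConfig:
    """Generator parameters; defaults give a sparse rural region.

    The default domain is 200 x 200 cells of 100 m (20 km x 20 km) holding
    100,000 people in 12 clustered settlements — sparse enough that uniform
    census-unit spreading pushes population far from facilities, the regime
    in which gridded products disagree most.
    """

    n_rows: int = 200
    n_cols: int = 200
    cell_size: float = 100.0
    crs_id: str = "local:metric"
    n_settlements: int = 12
    total_population: int = 100_000
    n_parents: int = 4  # cluster centres of the settlement point process
    parent_sigma_frac: float = 0.07  # settlement scatter around parents, fraction of width
    rural_fraction: float = 0.1  # share of households dispersed outside settlements
    footprint_sigma_cells: float = 1.5  # household scatter within a settlement
    n_rivers: int = 2
    n_lakes: int = 1
    lake_radius_cells: float = 4.0
    forest_fraction: float = 0.25
    forest_smooth_cells: float = 6.0
    facility_fraction: float = 0.3  # share of settlements hosting a facility
    admin1_nx: int = 3
    admin1_ny: int = 3
    admin2_nx: int = 2  # level-2 subdivision of each level-1 unit
    admin2_ny: int = 2

    def grid(self) -> GridSpec:
        return GridSpec(self.n_rows, self.n_cols, 0.0, self.n_rows * self.cell_size,
                        self.cell_size, self.crs_id)


@dataclass
class AllocationScheme:
    """How one emulated population product disaggregates census totals."""

    name: str
    kind: str  # constrained | unconstrained_uniform | unconstrained_covariate
    census_unit_level: int = 1  # 0 = whole domain, 1 or 2 = admin level
    detection_miss_rate: float = 0.0
    covariate_sigma_cells: float = 5.0
    covariate_noise_scale: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("constrained", "unconstrained_uniform", "unconstrained_covariate"):
            raise ValueError(f"unknown allocation kind {self.kind!r}")
        if self.census_unit_level not in (0, 1, 2):
            raise ValueError("census_unit_level must be 0 (whole domain), 1 or 2")
        if not 0 <= self.detection_miss_rate < 1:
            raise ValueError("detection_miss_rate must be in [0, 1)")
        if self.covariate_noise_scale < 0:
            raise ValueError("covariate_noise_scale must be >= 0")


def default_schemes() -> list[AllocationScheme]:
    """The three emulated product families at their default census coarseness.

    Constrained products typically work from fine census inputs (level 2);
    the unconstrained families are given the coarse level-1 units, standing
    in for countries whose census is only released at large units.
    """
    return [
        AllocationScheme("constrained", "constrained", census_unit_level=2,
                         detection_miss_rate=0.1),
        AllocationScheme("unconstrained_uniform", "unconstrained_uniform",
                         census_unit_level=1),
        AllocationScheme("unconstrained_covariate", "unconstrained_covariate",
                         census_unit_level=1),
    ]


@dataclass
class Settlement:
    center_x: float
    center_y: float
    n_households: int
    footprint_cells: set[tuple[int, int]] = field(default_factory=set)


@dataclass
class SyntheticWorld:
    grid: GridSpec
    landcover: np.ndarray
    water_mask: np.ndarray
    settlements: list[Settlement]
    households_xy: np.ndarray  # (n, 2) map coordinates, weight 1 person each
    roads: FeatureCollection
    rivers: FeatureCollection
    lakes: FeatureCollection
    facilities: FeatureCollection
    admin: dict[int, FeatureCollection]
    config: WorldConfig
    seed: int
    _cell_units: dict[int, np.ndarray] = field(default_factory=dict, repr=False)
    _tally: np.ndarray | None = field(default=None, repr=False)

    @property
    def total_population(self) -> int:
        return self.households_xy.shape[0]

    def household_tally(self) -> np.ndarray:
        """Household persons per cell (the ground-truth population lattice)."""
        if self._tally is None:
            row, col = self.grid.cell_of(self.households_xy[:, 0], self.households_xy[:, 1])
            tally = np.zeros(self.grid.shape)
            np.add.at(tally, (row, col), 1.0)
            self._tally = tally
        return self._tally

    def cell_unit_ids(self, level: int) -> np.ndarray:
        """Admin-unit id of each cell's centroid at the given level ('' outside)."""
        if level == 0:
            return np.full(self.grid.shape, "D", dtype=object)
        if level not in self._cell_units:
            x, y = self.grid.centroids()
            self._cell_units[level] = assign_units(
                x.ravel(), y.ravel(), self.admin[level]
            ).reshape(self.grid.shape)
        return self._cell_units[level]

    def land_mask(self) -> np.ndarray:
        return ~self.water_mask


@dataclass
class TrueCoverage:
    fraction: float
    pop_total: float  # non-barrier household persons
    pop_on_barrier: float


def _stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {name: np.random.default_rng(child) for name, child in zip(_STAGES, children)}


def _meander(rng: np.random.Generator, grid: GridSpec) -> LineString:
    """A river: a lateral random walk crossing the full domain."""
    minx, miny, maxx, maxy = grid.bounds
    vertical = bool(rng.integers(2))
    n_pts = 24
    along = np.linspace(0.0, 1.0, n_pts)
    start = rng.uniform(0.25, 0.75)
    lateral = start + np.cumsum(rng.normal(0.0, 0.035, n_pts))
    lateral = np.clip(lateral, 0.05, 0.95)
    if vertical:
        xs = minx + lateral * (maxx - minx)
        ys = maxy - along * (maxy - miny)
    else:
        xs = minx + along * (maxx - minx)
        ys = maxy - lateral * (maxy - miny)
    return LineString(np.column_stack([xs, ys]))


def _off_water(row: int, col: int, water: np.ndarray, radius: int = 10):
    """Nearest non-water cell within radius, ties row-major; None if all water."""
    if not water[row, col]:
        return row, col
    best = None
    for dr in range(-radius, radius + 1):
        for dc in range(-radius, radius + 1):
            r, c = row + dr, col + dc
            if 0 <= r < water.shape[0] and 0 <= c < water.shape[1] and not water[r, c]:
                key = (dr * dr + dc * dc, r, c)
                if best is None or key < best:
                    best = key
    if best is None:
        return None
    return best[1], best[2]


def _cuts(rng: np.random.Generator, n_parts: int, lo: int, hi: int) -> list[int]:
    """Random guillotine cut positions (cell indices) splitting [lo, hi) into n_parts.

    Widths are Dirichlet-distributed with a floor of 30% of the even split, so
    unit sizes genuinely vary (the size-vs-difference association needs
    heterogeneous areas) while no unit collapses to nothing.
    """
    span = hi - lo
    if n_parts <= 1 or span < 2 * n_parts:
        return [lo, hi]
    floor = 0.3 / n_parts
    widths = floor + (1.0 - n_parts * floor) * rng.dirichlet(np.full(n_parts, 1.5))
    edges = lo + np.round(np.cumsum(widths) * span).astype(int)
    edges[-1] = hi
    cuts = [lo]
    for e in edges:
        cuts.append(max(int(e), cuts[-1] + 1))
    cuts[-1] = hi
    return cuts


def _admin_partition(rng: np.random.Generator, grid: GridSpec, cfg: WorldConfig):
    """Nested rectangular partition snapped to cell boundaries."""

    def cell_box(r0, r1, c0, c1):
        return box(
            grid.origin_x + c0 * grid.cell_size,
            grid.origin_y - r1 * grid.cell_size,
            grid.origin_x + c1 * grid.cell_size,
            grid.origin_y - r0 * grid.cell_size,
        )

    row_cuts = _cuts(rng, cfg.admin1_ny, 0, grid.n_rows)
    col_cuts = _cuts(rng, cfg.admin1_nx, 0, grid.n_cols)
    level1, level2 = [], []
    for i in range(len(row_cuts) - 1):
        for j in range(len(col_cuts) - 1):
            r0, r1 = row_cuts[i], row_cuts[i + 1]
            c0, c1 = col_cuts[j], col_cuts[j + 1]
            a1_id = f"A{i * (len(col_cuts) - 1) + j:02d}"
            level1.append(Feature(cell_box(r0, r1, c0, c1), {"admin_id": a1_id}))
            sub_rows = _cuts(rng, cfg.admin2_ny, r0, r1)
            sub_cols = _cuts(rng, cfg.admin2_nx, c0, c1)
            k = 0
            for si in range(len(sub_rows) - 1):
                for sj in range(len(sub_cols) - 1):
                    level2.append(
                        Feature(
                            cell_box(sub_rows[si], sub_rows[si + 1],
                                     sub_cols[sj], sub_cols[sj + 1]),
                            {"admin_id": f"{a1_id}-{k:02d}", "parent_id": a1_id},
                        )
                    )
                    k += 1
    return (
        FeatureCollection(level1, crs_id=grid.crs_id),
        FeatureCollection(level2, crs_id=grid.crs_id),
    )


def make_world(config: WorldConfig | None = None, seed: int = 0) -> SyntheticWorld:
    """Generate a reproducible synthetic world; same (config, seed) → same world."""
    cfg = config or WorldConfig()
    if cfg.n_settlements < 1:
        raise ValueError("at least one settlement is required (facilities must be placeable)")
    if cfg.n_rows * cfg.n_cols < 25 * cfg.n_settlements:
        raise ValueError(
            f"domain of {cfg.n_rows}x{cfg.n_cols} cells is too small to place "
            f"{cfg.n_settlements} settlements"
        )
    grid = cfg.grid()
    rngs = _stage_rngs(seed)
    minx, miny, maxx, maxy = grid.bounds
    width, height = maxx - minx, maxy - miny

    # water first, so settlements and households can avoid it
    rivers = FeatureCollection(
        [Feature(_meander(rngs["rivers"], grid), {"class": "river"})
         for _ in range(cfg.n_rivers)],
        crs_id=grid.crs_id,
    )
    lake_feats = []
    for _ in range(cfg.n_lakes):
        cx = rngs["lakes"].uniform(minx + 0.1 * width, maxx - 0.1 * width)
        cy = rngs["lakes"].uniform(miny + 0.1 * height, maxy - 0.1 * height)
        lake_feats.append(
            Feature(Point(cx, cy).buffer(cfg.lake_radius_cells * cfg.cell_size),
                    {"class": "lake"})
        )
    lakes = FeatureCollection(lake_feats, crs_id=grid.crs_id)
    water_mask = rasterize_barriers(rivers, lakes, grid)

    # clustered settlement centres (parent–child process), nudged off water
    rng_s = rngs["settlements"]
    margin = 0.05
    parents = np.column_stack(
        [
            rng_s.uniform(minx + margin * width, maxx - margin * width, cfg.n_parents),
            rng_s.uniform(miny + margin * height, maxy - margin * height, cfg.n_parents),
        ]
    )
    which = rng_s.integers(0, cfg.n_parents, cfg.n_settlements)
    centers = parents[which] + rng_s.normal(0.0, cfg.parent_sigma_frac * width,
                                            (cfg.n_settlements, 2))
    centers[:, 0] = np.clip(centers[:, 0], minx + margin * width, maxx - margin * width)
    centers[:, 1] = np.clip(centers[:, 1], miny + margin * height, maxy - margin * height)
    fixed_centers = []
    for cx, cy in centers:
        row, col = grid.cell_of(cx, cy)
        moved = _off_water(int(row), int(col), water_mask)
        if moved is None:
            raise ValueError("could not place a settlement on land; too much water")
        if moved != (int(row), int(col)):
            cx, cy = grid.cell_centroid(*moved)
        fixed_centers.append((float(cx), float(cy)))

    # households: exact multinomial split of the configured total; a rural
    # share is dispersed over the whole land surface, the rest clusters in
    # settlement footprints
    rng_h = rngs["households"]
    if not 0 <= cfg.rural_fraction < 1:
        raise ValueError("rural_fraction must be in [0, 1)")
    n_rural = int(round(cfg.rural_fraction * cfg.total_population))
    sizes = rng_h.lognormal(0.0, 0.8, cfg.n_settlements)
    counts = rng_h.multinomial(cfg.total_population - n_rural, sizes / sizes.sum())
    settlements = [
        Settlement(cx, cy, int(n)) for (cx, cy), n in zip(fixed_centers, counts)
    ]
    sigma = cfg.footprint_sigma_cells * cfg.cell_size
    all_xy = []
    for s in settlements:
        if s.n_households == 0:
            continue
        xy = np.empty((s.n_households, 2))
        todo = np.arange(s.n_households)
        for _ in range(60):
            if todo.size == 0:
                break
            cand = np.column_stack(
                [
                    rng_h.normal(s.center_x, sigma, todo.size),
                    rng_h.normal(s.center_y, sigma, todo.size),
                ]
            )
            row, col = grid.cell_of(cand[:, 0], cand[:, 1])
            ok = (row >= 0) & ~water_mask[np.clip(row, 0, None), np.clip(col, 0, None)]
            xy[todo[ok]] = cand[ok]
            todo = todo[~ok]
        if todo.size:  # pathological geometry: park the rest on the centre cell
            xy[todo] = (s.center_x, s.center_y)
        all_xy.append(xy)
        row, col = grid.cell_of(xy[:, 0], xy[:, 1])
        s.footprint_cells = set(zip(row.tolist(), col.tolist()))
    if n_rural:
        xy = np.empty((n_rural, 2))
        todo = np.arange(n_rural)
        for _ in range(60):
            if todo.size == 0:
                break
            cand = np.column_stack(
                [rng_h.uniform(minx, maxx, todo.size), rng_h.uniform(miny, maxy, todo.size)]
            )
            row, col = grid.cell_of(cand[:, 0], cand[:, 1])
            ok = (row >= 0) & ~water_mask[np.clip(row, 0, None), np.clip(col, 0, None)]
            xy[todo[ok]] = cand[ok]
            todo = todo[~ok]
        if todo.size:
            xy[todo] = fixed_centers[0]
        all_xy.append(xy)
    households_xy = np.vstack(all_xy) if all_xy else np.empty((0, 2))

    # roads: nearest-neighbour links plus a spanning tree, classed by role
    road_feats = []
    if cfg.n_settlements >= 2:
        pts = np.array([(s.center_x, s.center_y) for s in settlements])
        dist = cdist(pts, pts)
        mst = minimum_spanning_tree(dist).tocoo()
        edges = {(min(i, j), max(i, j)): CLASS_ROAD_PRIMARY
                 for i, j in zip(mst.row.tolist(), mst.col.tolist())}
        np.fill_diagonal(dist, np.inf)
        for i, j in enumerate(np.argmin(dist, axis=1).tolist()):
            edges.setdefault((min(i, j), max(i, j)), CLASS_ROAD_SECONDARY)
        for (i, j), code in sorted(edges.items()):
            road_feats.append(
                Feature(LineString([pts[i], pts[j]]), {"class_code": int(code)})
            )
    roads = FeatureCollection(road_feats, crs_id=grid.crs_id)

    # facilities at a subset of settlement centres, drawn without replacement
    n_fac = max(1, int(round(cfg.facility_fraction * cfg.n_settlements)))
    fac_idx = rngs["facilities"].choice(cfg.n_settlements, size=n_fac, replace=False)
    facilities = FeatureCollection(
        [
            Feature(Point(settlements[i].center_x, settlements[i].center_y),
                    {"facility_id": f"F{k:02d}", "settlement": int(i)})
            for k, i in enumerate(sorted(fac_idx.tolist()))
        ],
        crs_id=grid.crs_id,
    )

    admin1, admin2 = _admin_partition(rngs["admin"], grid, cfg)

    # land cover: open terrain with smoothed-noise forest, settlement and water classes
    noise = gaussian_filter(rngs["landcover"].standard_normal(grid.shape),
                            cfg.forest_smooth_cells)
    landcover = np.full(grid.shape, CLASS_OPEN, dtype=np.int64)
    if cfg.forest_fraction > 0:
        landcover[noise >= np.quantile(noise, 1.0 - cfg.forest_fraction)] = CLASS_FOREST
    for s in settlements:
        for r, c in s.footprint_cells:
            landcover[r, c] = CLASS_SETTLEMENT
    landcover[water_mask] = CLASS_WATER

    return SyntheticWorld(
        grid=grid, landcover=landcover, water_mask=water_mask,
        settlements=settlements, households_xy=households_xy,
        roads=roads, rivers=rivers, lakes=lakes, facilities=facilities,
        admin={1: admin1, 2: admin2}, config=cfg, seed=seed,
    )


def allocate_population(
    world: SyntheticWorld,
    scheme: AllocationScheme,
    target_grid: GridSpec | None = None,
    seed: int | None = None,
) -> PopulationGrid:
    """Build one emulated gridded population product from the world's truth.

    Allocation happens on the world grid — per census unit, the true
    household total of the unit is redistributed according to the scheme, so
    unit totals are preserved exactly — and is then block-summed to
    ``target_grid`` if that is an integer coarsening of the world grid.
    """
    grid = world.grid
    # crc32 gives a process-independent per-scheme substream of the one seed
    rng = np.random.default_rng(
        np.random.SeedSequence([world.seed if seed is None else seed,
                                zlib.crc32(scheme.name.encode())])
    )
    tally = world.household_tally()
    unit_ids = world.cell_unit_ids(scheme.census_unit_level)
    land = world.land_mask()

    if scheme.kind == "constrained":
        detected = rng.random(len(world.settlements)) >= scheme.detection_miss_rate
        det_mask = np.zeros(grid.shape, dtype=bool)
        for s, keep in zip(world.settlements, detected):
            if keep:
                for r, c in s.footprint_cells:
                    det_mask[r, c] = True
        weights = np.where(det_mask, tally, 0.0)
    elif scheme.kind == "unconstrained_uniform":
        weights = land.astype(float)
    else:  # unconstrained_covariate
        indicator = (tally > 0).astype(float)
        cov = gaussian_filter(indicator, scheme.covariate_sigma_cells)
        noise = rng.lognormal(0.0, scheme.covariate_noise_scale, grid.shape)
        weights = cov * noise

    out = np.zeros(grid.shape)
    fallback_units = []
    for uid in np.unique(unit_ids[unit_ids != ""]):
        sel = unit_ids == uid
        total = float(tally[sel].sum())
        if total == 0:
            continue
        w = np.where(sel, weights, 0.0)
        wsum = w.sum()
        if wsum > 0:
            out += total * w / wsum
        else:
            fallback = sel & land
            if not fallback.any():
                fallback = sel
            fallback_units.append(uid)
            out[fallback] += total / fallback.sum()
    if fallback_units:
        log.warning(
            "scheme %s: %d unit(s) with no allocation weight (no detected footprint); "
            "population spread uniformly there: %s",
            scheme.name, len(fallback_units), ", ".join(fallback_units[:8]),
        )

    pop = PopulationGrid(values=out, grid=grid, name=scheme.name)
    if target_grid is None or target_grid.same_lattice(grid):
        return pop
    return _coarsen_pop(pop, target_grid)


def _coarsen_pop(pop: PopulationGrid, target: GridSpec) -> PopulationGrid:
    grid = pop.grid
    factor = target.cell_size / grid.cell_size
    if (
        abs(factor - round(factor)) > 1e-9
        or abs(target.origin_x - grid.origin_x) > 1e-6
        or abs(target.origin_y - grid.origin_y) > 1e-6
        or target.crs_id != grid.crs_id
        or not grid.coarsen(int(round(factor))).same_lattice(target)
    ):
        raise ValueError("target grid must be the world grid or an integer coarsening of it")
    factor = int(round(factor))
    padded = np.zeros((target.n_rows * factor, target.n_cols * factor))
    padded[: grid.n_rows, : grid.n_cols] = pop.values
    coarse = padded.reshape(target.n_rows, factor, target.n_cols, factor).sum(axis=(1, 3))
    return PopulationGrid(values=coarse, grid=target, name=pop.name)


def true_coverage(world: SyntheticWorld, travel: TravelTimeGrid, threshold_min: float) -> TrueCoverage:
    """Ground-truth coverage: household mass whose cell is within the threshold.

    Households on barrier cells are excluded from numerator and denominator
    and reported separately; unreachable-on-land households stay in the
    denominator.
    """
    if not travel.grid.same_lattice(world.grid):
        raise ValueError("travel-time grid does not match the world grid")
    tally = world.household_tally()
    on_barrier = float(tally[travel.barrier_mask].sum())
    denom = float(tally[~travel.barrier_mask].sum())
    with np.errstate(invalid="ignore"):
        covered_mask = ~travel.barrier_mask & (travel.minutes <= threshold_min)
    covered = float(tally[covered_mask].sum())
    fraction = covered / denom if denom > 0 else float("nan")
    return TrueCoverage(fraction=fraction, pop_total=denom, pop_on_barrier=on_barrier)


def unit_areas_km2(admin: FeatureCollection, id_attr: str = "admin_id") -> dict[str, float]:
    """Polygon areas in km² on the run's metric plane."""
    return {str(f.attrs[id_attr]): f.geometry.area / 1e6 for f in admin}


def export_world(world: SyntheticWorld, outdir, include_households: bool = True) -> dict:
    """Write the world's layers to a directory and return the manifest.

    Layers: landcover ASCII grid, roads/rivers/lakes/facilities/admin
    GeoJSON, households CSV (x, y, one person each), and a manifest YAML
    naming every member together with the generating config and seed.
    """
    from .rasters import write_raster  # local import to avoid cycle at module load

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_raster(outdir / "landcover.asc", world.landcover, world.grid)
    members = {"landcover": "landcover.asc"}
    for name, fc in (
        ("roads", world.roads), ("rivers", world.rivers), ("lakes", world.lakes),
        ("facilities", world.facilities),
        ("admin1", world.admin[1]), ("admin2", world.admin[2]),
    ):
        write_vectors(outdir / f"{name}.geojson", fc.features, crs_id=fc.crs_id)
        members[name] = f"{name}.geojson"
    if include_households:
        np.savetxt(
            outdir / "households.csv", world.households_xy,
            delimiter=",", header="x,y", comments="", fmt="%.3f",
        )
        members["households"] = "households.csv"
    manifest = {
        "members": members,
        "seed": world.seed,
        "config": {k: v for k, v in vars(world.config).items()},
        "crs_id": world.grid.crs_id,
    }
    (outdir / "manifest.yml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return manifest
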