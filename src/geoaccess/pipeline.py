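"""Stage functions tying the pipeline together.

Each stage reads the previous stage's files from a run directory and writes
its own, so stages can be re-run independently; `run_world` chains everything
in memory for programmatic use (tests, batch experiments).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .compare import average_unit_diff, pairwise_diff, size_association
from .config import RunConfig
from .coverage import barrier_report, coverage_stats
from .friction import FrictionGrid, build_friction, merge_layers, rasterize_barriers, \
    rasterize_lines, resolve_scenario
from .population import PopulationGrid, classify_points, harmonize, to_points
from .rasters import DEFAULT_NODATA, read_raster, write_raster
from .scenario import CLASS_WATER, DEFAULT_ROAD_FALLBACK_KMH, DEFAULT_SCENARIO, \
    read_scenario, write_scenario
from .synthetic import AllocationScheme, SyntheticWorld, allocate_population, \
    default_schemes, export_world, make_world, true_coverage, unit_areas_km2, WorldConfig
from .travel import TravelTimeGrid, UNREACHABLE, least_cost_travel_time, seed_facilities
from .vectors import read_vectors

__all__ = [
    "simulate_stage", "friction_stage", "traveltime_stage", "coverage_stage",
    "compare_stage", "run_world", "MissingInputError",
    "build_world_friction", "write_travel_time", "read_travel_time",
]

log = logging.getLogger(__name__)


class MissingInputError(FileNotFoundError):
    """A stage was invoked before the stage producing its inputs."""


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise MissingInputError(
            f"required input {path.name} not found in {path.parent}; "
            f"run the '{producer}' stage first"
        )
    return path


def _schemes_from_config(cfg: RunConfig) -> list[AllocationScheme]:
    if not cfg.schemes:
        return default_schemes()
    return [AllocationScheme(**s) for s in cfg.schemes]


def _scenario_from_config(cfg: RunConfig):
    return read_scenario(cfg.scenario_path) if cfg.scenario_path else DEFAULT_SCENARIO


# ---------------------------------------------------------------------------
# in-memory helpers

def build_world_friction(world: SyntheticWorld, scenario=None) -> FrictionGrid:
    """Rasterize the world's layers and assemble its friction surface."""
    scenario = scenario or DEFAULT_SCENARIO
    road_classes = rasterize_lines(world.roads, world.grid, scenario.speeds())
    barrier = rasterize_barriers(world.rivers, world.lakes, world.grid)
    merged = merge_layers(world.landcover, road_classes, barrier, world.grid,
                          barrier_class=CLASS_WATER)
    complete = resolve_scenario(scenario, np.unique(merged.classes),
                                DEFAULT_ROAD_FALLBACK_KMH)
    return build_friction(merged, complete)


def run_world(
    world: SyntheticWorld,
    schemes: list[AllocationScheme] | None = None,
    thresholds_min=(30, 60, 90, 120, 150, 180),
    levels: tuple[int, ...] = (0, 1, 2),
    scenario=None,
    snap_radius_cells: int = 5,
) -> dict:
    """World → friction → travel time → per-scheme coverage, all in memory.

    Returns a dict with the travel-time grid, the classified points, the
    coverage and barrier tables, and per-threshold ground-truth coverage.
    """
    schemes = schemes if schemes is not None else default_schemes()
    friction = build_world_friction(world, scenario)
    seeds = seed_facilities(world.facilities, friction, snap_radius_cells)
    travel = least_cost_travel_time(friction, seeds)

    point_frames = []
    for scheme in schemes:
        pop = allocate_population(world, scheme)
        pop, _ = harmonize(pop, world.admin[2], land_mask=world.land_mask())
        pts = to_points(pop)
        point_frames.append(classify_points(pts, travel, world.admin, levels=(1, 2)))
    points = pd.concat(point_frames, ignore_index=True)

    table = coverage_stats(points, thresholds_min, levels=levels)
    truth = {t: true_coverage(world, travel, t) for t in thresholds_min}
    return {
        "friction": friction,
        "travel": travel,
        "points": points,
        "coverage": table,
        "barrier": barrier_report(points),
        "truth": truth,
    }


# ---------------------------------------------------------------------------
# travel-time raster round trip: barrier -> nodata, unreachable -> -1 sentinel

def write_travel_time(path, travel: TravelTimeGrid) -> None:
    values = travel.minutes.copy()
    values[travel.unreachable_mask] = UNREACHABLE
    values[travel.barrier_mask] = np.nan  # serialized as nodata
    write_raster(path, values, travel.grid)


def read_travel_time(path) -> TravelTimeGrid:
    raster = read_raster(path)
    barrier = raster.nodata_mask
    minutes = raster.values.astype(float).copy()
    minutes[minutes == UNREACHABLE] = np.inf
    minutes[barrier] = np.nan
    return TravelTimeGrid(minutes=minutes, barrier_mask=barrier, grid=raster.grid)


# ---------------------------------------------------------------------------
# file-based stages

def simulate_stage(cfg: RunConfig, outdir: Path) -> SyntheticWorld:
    outdir = Path(outdir)
    world = make_world(WorldConfig(**cfg.world), seed=cfg.seed)
    manifest = export_world(world, outdir)
    datasets = {}
    for scheme in _schemes_from_config(cfg):
        pop = allocate_population(world, scheme)
        fname = f"population_{scheme.name}.asc"
        write_raster(outdir / fname, pop.values, pop.grid)
        datasets[scheme.name] = fname
    manifest["datasets"] = datasets
    (outdir / "manifest.yml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    write_scenario(outdir / "scenario.csv", _scenario_from_config(cfg))
    log.info("simulate: world seed=%d, %d datasets -> %s", cfg.seed, len(datasets), outdir)
    return world


def friction_stage(cfg: RunConfig, outdir: Path) -> FrictionGrid:
    outdir = Path(outdir)
    landcover = read_raster(_require(outdir / "landcover.asc", "simulate"))
    roads = read_vectors(_require(outdir / "roads.geojson", "simulate"), "line")
    rivers = read_vectors(_require(outdir / "rivers.geojson", "simulate"), "line")
    lakes = read_vectors(_require(outdir / "lakes.geojson", "simulate"), "polygon")
    scenario = read_scenario(_require(outdir / "scenario.csv", "simulate"))

    grid = landcover.grid
    road_classes = rasterize_lines(roads, grid, scenario.speeds())
    barrier = rasterize_barriers(rivers, lakes, grid)
    merged = merge_layers(landcover.values.astype(np.int64), road_classes, barrier,
                          grid, barrier_class=CLASS_WATER)
    complete = resolve_scenario(scenario, np.unique(merged.classes),
                                DEFAULT_ROAD_FALLBACK_KMH)
    friction = build_friction(merged, complete)
    write_raster(outdir / "merged_classes.asc", merged.classes, grid)
    write_raster(outdir / "friction.asc",
                 np.where(friction.barrier_mask, np.nan, friction.minutes), grid)
    return friction


def _read_friction(outdir: Path) -> FrictionGrid:
    raster = read_raster(_require(Path(outdir) / "friction.asc", "friction"))
    barrier = raster.nodata_mask
    minutes = np.where(barrier, np.nan, raster.values.astype(float))
    return FrictionGrid(minutes=minutes, barrier_mask=barrier, grid=raster.grid)


def traveltime_stage(cfg: RunConfig, outdir: Path) -> TravelTimeGrid:
    outdir = Path(outdir)
    friction = _read_friction(outdir)
    facilities = read_vectors(_require(outdir / "facilities.geojson", "simulate"), "point")
    seeds = seed_facilities(facilities, friction, cfg.snap_radius_cells)
    travel = least_cost_travel_time(friction, seeds)
    write_travel_time(outdir / "travel_time.asc", travel)
    return travel


def coverage_stage(cfg: RunConfig, outdir: Path) -> pd.DataFrame:
    outdir = Path(outdir)
    travel = read_travel_time(_require(outdir / "travel_time.asc", "traveltime"))
    admin = {
        1: read_vectors(_require(outdir / "admin1.geojson", "simulate"), "polygon"),
        2: read_vectors(_require(outdir / "admin2.geojson", "simulate"), "polygon"),
    }
    manifest_path = _require(outdir / "manifest.yml", "simulate")
    manifest = yaml.safe_load(manifest_path.read_text())
    datasets = dict(cfg.datasets) or manifest.get("datasets", {})
    if not datasets:
        raise MissingInputError("no population datasets registered in config or manifest")

    frames = []
    for name, rel in sorted(datasets.items()):
        raster = read_raster(outdir / rel if not Path(rel).is_absolute() else rel)
        values = np.where(raster.nodata_mask, np.nan, raster.values.astype(float))
        pop = PopulationGrid(values=values, grid=raster.grid, name=name)
        pop, _ = harmonize(pop, admin[2])
        pts = to_points(pop)
        frames.append(classify_points(pts, travel, admin, levels=(1, 2)))
    points = pd.concat(frames, ignore_index=True)

    table = coverage_stats(points, cfg.thresholds_min, levels=cfg.admin_levels)
    out = table.copy()
    out["coverage_pct"] = out["coverage_pct"].round(1)  # report precision, 1 dp
    out.to_csv(outdir / "coverage.csv", index=False, float_format="%.6f")
    barrier_report(points).to_csv(outdir / "barrier.csv", index=False, float_format="%.6f")
    return table


def compare_stage(cfg: RunConfig, outdir: Path) -> dict:
    outdir = Path(outdir)
    table = pd.read_csv(_require(outdir / "coverage.csv", "coverage"))
    admin1 = read_vectors(_require(outdir / "admin1.geojson", "simulate"), "polygon")
    areas = unit_areas_km2(admin1)

    rows = []
    for thr in cfg.thresholds_min:
        mat = pairwise_diff(table, thr, level=0)
        for a in mat.index:
            for b in mat.columns:
                if a < b:
                    rows.append({"threshold_min": thr, "dataset_a": a, "dataset_b": b,
                                 "diff_pp": mat.loc[a, b]})
    pd.DataFrame(rows).to_csv(outdir / "pairwise.csv", index=False, float_format="%.6f")

    assoc: dict = {}
    unit_thr = 60 if 60 in cfg.thresholds_min else cfg.thresholds_min[0]
    if 1 in cfg.admin_levels and table["dataset"].nunique() >= 2:
        unit_diff = average_unit_diff(table, unit_thr, level=1, areas_km2=areas)
        unit_diff.to_csv(outdir / "unit_diff.csv", index=False, float_format="%.6f")
        if len(unit_diff) >= 5:
            assoc = size_association(unit_diff)
            (outdir / "association.yml").write_text(yaml.safe_dump(assoc, sort_keys=True))
    return assoc
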