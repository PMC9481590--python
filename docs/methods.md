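# Methods

## Scope and model

`geoaccess` measures geographic accessibility of health facilities as
least-cost travel time over a friction surface, and the sensitivity of
accessibility *coverage* statistics to the gridded population dataset used
as denominator. The pipeline has five stages: friction-surface construction,
travel-time computation, population harmonization, zonal coverage
statistics, and cross-dataset comparison. A synthetic-world generator
provides inputs with known ground truth.

## Friction surface

Land cover, rasterized roads and water barriers merge with the fixed
priority **road > barrier > land cover**: a cell a road passes through keeps
the road class even over water (bridges/fords), remaining water cells are
impassable, everything else keeps its land-cover class. Rationale for the
rasterization dialects:

* **Roads: all-touched** (every cell whose box the line intersects). At
  100 m resolution a centre-line rule breaks connectivity on diagonal
  segments; all-touched keeps the rasterized road traversable.
* **Overlapping roads: fastest class wins**, which preserves the fast
  road's connectivity; the number of affected cells is logged.
* **River lines: all-touched; water polygons: centroid coverage.** A
  narrow river must remain a continuous barrier at coarse resolution, while
  centroid coverage avoids inflating lake edges. Minor streams are assumed
  excluded upstream by the data-preparation contract (they can be crossed).

Crossing time per cell is `(cell_size/1000)/speed × 60` minutes, using
motorized speeds on roads and walking speeds off-road. Default scenario:
open terrain 5 km/h, dense forest 2 km/h, settlement 5 km/h, primary /
secondary / tertiary roads 80 / 50 / 30 km/h, water barrier. Road classes
missing from a user scenario are filled from a fallback table of average
road-class speeds and logged; a class with neither entry is a hard error.
The stored surface is direction-free (isotropic; no slope correction).

## Travel time

The friction grid induces a graph on non-barrier cells, 8-connected, with
edge weight `(t_a + t_b)/2` (× √2 on diagonals) — the standard cost-surface
transition of the r.cost / AccessMod family. The choice of an **exact
multi-source Dijkstra** (scipy's compiled csgraph implementation) rather
than an approximate spreading algorithm makes results deterministic and
verifiable: the test suite checks every cell of hundreds of random grids
against an independently written brute-force Dijkstra (tolerance 1e-9 min)
and against the octile closed form `t·(max(|dr|,|dc|) + (√2−1)·min)` on
uniform grids.

Facilities map to their containing cell (half-open extents, north-west
origin). A facility on a barrier cell snaps to the nearest non-barrier cell
within a configurable radius (default 5 cells; Euclidean cell distance,
ties broken row-major); unsnappable facilities and facilities outside the
grid are dropped with a logged count. Unreachable land cells are reported
distinctly from barrier cells (in rasters: −1 sentinel vs the nodata
marker), because downstream they are treated oppositely — unreachable
population stays in coverage denominators, barrier population does not.

## Population harmonization and points

Products arrive at their native resolution and are never resampled.
Harmonization clips to the level-2 region and rescales each level-2 unit
multiplicatively so its total matches the original product exactly.
"Restoring lost mass" by *proportional* rescaling (rather than an additive
uniform spread) preserves the within-unit spatial pattern — an additive
spread would fill the deliberate zero cells of constrained products. A unit
whose processed total is zero but whose original total is positive receives
the original total spread uniformly over its land cells, with a warning
(mirroring the fallback behaviour of real products). Harmonized grids
become one point per positive cell at the cell centroid; each point takes
the travel time of its containing cell and admin ids by point-in-polygon
(on-edge ties go to the first polygon in stable id order). Every point ends
in exactly one state: finite travel time, barrier, unreachable, or
out-of-region.

The pipeline is deliberately **single-CRS**: all layers of a run must share
one projected metric CRS, and mixed grids are refused rather than silently
resampled or reprojected. Rasters are exchanged as ESRI ASCII Grid — a
plain-text, GDAL/QGIS-readable format — with a `.prj` sidecar carrying the
CRS identifier; vectors as GeoJSON with an explicit `crs_id` member.

## Coverage statistics

Per (dataset, admin level, unit, threshold): covered = population with
travel time ≤ threshold; total = population excluding barrier and
out-of-region mass, *including* unreachable-on-land mass. This denominator
convention is verified against the published continental summary table the
statistic is modelled on: recomputing relative coverage from its printed
absolute counts reproduces the printed one-decimal percentages for all six
products at all six thresholds. Units with zero non-barrier population are
marked undefined rather than 0%. Internal arithmetic is full precision;
rounding to one decimal happens only at CSV serialization.

"Difference" between datasets is the absolute difference in coverage
percentage points. A ratio definition was rejected: it diverges in
low-coverage units and does not match the magnitudes (tens of percentage
points) the comparison is meant to surface. Unit areas are computed on the
run's metric plane (the run CRS is taken as the equal-area projection);
population quantiles are quartiles of the across-dataset mean unit total.

## Synthetic worlds

The generator emulates the structure of the real inputs, not any specific
product's algorithm:

* **Settlements** follow a parent–child (Thomas-like) process — 4 parents,
  12 settlements, scatter 7% of the domain width — so some admin units are
  dense and others nearly empty, the regime where population products
  disagree most. Household positions scatter around centres (σ = 1.5
  cells); 10% of households are dispersed rural population, uniform over
  land, so no unit is exactly empty (as in real censuses).
* **Default domain**: 200 × 200 cells of 100 m (20 km × 20 km), 100,000
  people, 2 rivers, 1 lake, facilities at 30% of settlements. The
  population total is split exactly (multinomial), so conservation checks
  are exact.
* **Admin partition**: nested random guillotine rectangles (3 × 3 level-1
  units, each split 2 × 2 into level-2), widths Dirichlet-distributed with
  a floor at 30% of the even split — unit areas genuinely vary, which the
  area-vs-difference association needs, but no unit degenerates.
* **Allocation schemes**: `constrained` (level-2 census units, whole
  settlements missed with probability 0.1, mass proportional to true
  footprint density); `unconstrained_uniform` (level-1 units, equal share
  per land cell); `unconstrained_covariate` (level-1 units, Gaussian-
  smoothed settlement indicator, σ = 5 cells, lognormal noise scale 0.5 —
  chosen to sit between the other two, and the only scheme allowed to put
  mass on water, emulating the higher barrier population of unconstrained
  products). Census-unit coarseness (level 2 vs level 1 vs whole domain)
  stands in for the granularity of publicly released census data.
* **Randomness**: one master seed, split into named per-stage substreams
  (rivers, lakes, settlements, households, roads, facilities, admin, land
  cover) via `numpy` SeedSequence spawning, plus a CRC-keyed substream per
  allocation scheme — each stage is independently reproducible.

What the generator does *not* emulate: real products' actual algorithms
(random-forest dasymetric weights, night lights), real population
magnitudes, multi-country CRS mosaics, or facility-type stratification.
Passing tests therefore show that the *pipeline* is correct and that the
constrained-vs-unconstrained mechanism behaves as in the published
analyses; they do not validate any real product.

## Problem sizes and numerical conventions

The acceptance batch runs 20 worlds at the default 200 × 200 / 100k-person
conditions (~15 s total); the oracle suite checks 200 random grids up to
50 × 50 against brute force. Tolerances: travel time 1e-9 min against the
oracle; population conservation exact per census unit at allocation, 1e-6
relative end-to-end through points; aggregation consistency 1e-6 relative.
Degenerate inputs are defined, not guessed: empty vector layers warn and
return empty collections; an all-missed census unit falls back to uniform
spread with a warning; constant inputs to the rank correlation yield NaN;
zero-population units yield undefined coverage.

## Known limitations

Isotropic travel only (no slope or seasonal effects); no cross-border
travel (the grid is the study region); no travel-speed uncertainty bounds;
no reallocation of barrier population; no reprojection engine (one metric
CRS per run, by design); facility snapping behaviour beyond the configured
radius is a drop, not a search.
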