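"""Synthetic worlds: determinism, conservation, allocation schemes, ground truth."""

import numpy as np
import pytest

from geoaccess import (
    AllocationScheme,
    WorldConfig,
    allocate_population,
    least_cost_travel_time,
    make_world,
    true_coverage,
)
from geoaccess.friction import FrictionGrid
from geoaccess.grid import GridSpec
from geoaccess.pipeline import build_world_friction
from geoaccess.travel import FacilitySeedSet, TravelTimeGrid

CFG = WorldConfig(n_rows=80, n_cols=80, n_settlements=8, total_population=20_000)


class TestMakeWorld:
    def test_same_seed_same_world(self):
        w1, w2 = make_world(CFG, seed=1), make_world(CFG, seed=1)
        np.testing.assert_array_equal(w1.landcover, w2.landcover)
        np.testing.assert_array_equal(w1.households_xy, w2.households_xy)
        assert [f.geometry.wkt for f in w1.roads] == [f.geometry.wkt for f in w2.roads]
        assert [f.attrs for f in w1.facilities] == [f.attrs for f in w2.facilities]

    def test_different_seed_different_world(self):
        w1, w2 = make_world(CFG, seed=1), make_world(CFG, seed=2)
        assert not np.array_equal(w1.households_xy, w2.households_xy)

    def test_zero_settlements_rejected(self):
        with pytest.raises(ValueError):
            make_world(WorldConfig(n_settlements=0), seed=1)

    def test_domain_too_small_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            make_world(WorldConfig(n_rows=10, n_cols=10, n_settlements=50), seed=1)

    def test_population_total_exact(self, small_world):
        assert small_world.total_population == 20_000
        assert small_world.household_tally().sum() == 20_000

    def test_households_on_land_and_in_one_unit_per_level(self, small_world):
        w = small_world
        row, col = w.grid.cell_of(w.households_xy[:, 0], w.households_xy[:, 1])
        assert (row >= 0).all()
        assert not w.water_mask[row, col].any()
        for level in (1, 2):
            units = w.cell_unit_ids(level)[row, col]
            assert (units != "").all()

    def test_footprints_are_nonbarrier_and_facilities_at_settlements(self, small_world):
        w = small_world
        centers = {(s.center_x, s.center_y) for s in w.settlements}
        for f in w.facilities:
            assert (f.geometry.x, f.geometry.y) in centers
        for s in w.settlements:
            for r, c in s.footprint_cells:
                assert not w.water_mask[r, c]

    def test_landcover_contains_required_classes(self, small_world):
        present = set(np.unique(small_world.landcover).tolist())
        assert {1, 2, 3, 200} <= present  # open, forest, settlement, water

    def test_admin2_nests_in_admin1(self, small_world):
        parents = {f.attrs["admin_id"]: f.geometry for f in small_world.admin[1]}
        for f in small_world.admin[2]:
            parent = parents[f.attrs["parent_id"]]
            assert parent.covers(f.geometry)


UNIFORM = AllocationScheme("u", "unconstrained_uniform", census_unit_level=1)
CONSTRAINED = AllocationScheme("c", "constrained", census_unit_level=2,
                               detection_miss_rate=0.0)
COVARIATE = AllocationScheme("v", "unconstrained_covariate", census_unit_level=1)


class TestAllocatePopulation:
    def test_uniform_equal_split_over_nonwater_cells(self):
        # hand world: 2x2 grid, one unit, 1000 people, no water -> 250 per cell
        w = make_world(CFG, seed=3)
        unit_ids = w.cell_unit_ids(1)
        pop = allocate_population(w, UNIFORM)
        for uid in np.unique(unit_ids):
            sel = (unit_ids == uid) & w.land_mask()
            if sel.any():
                vals = pop.values[sel]
                np.testing.assert_allclose(vals, vals[0])  # equal share within unit

    @pytest.mark.parametrize("scheme", [UNIFORM, CONSTRAINED, COVARIATE],
                             ids=lambda s: s.kind)
    def test_census_unit_totals_preserved(self, small_world, scheme):
        w = small_world
        pop = allocate_population(w, scheme)
        tally = w.household_tally()
        unit_ids = w.cell_unit_ids(scheme.census_unit_level)
        for uid in np.unique(unit_ids):
            sel = unit_ids == uid
            np.testing.assert_allclose(pop.values[sel].sum(), tally[sel].sum(),
                                       rtol=1e-9, atol=1e-9)
        np.testing.assert_allclose(pop.total, w.total_population, rtol=1e-9)

    def test_constrained_support_only_on_footprints(self):
        # without dispersed rural population every populated unit holds a
        # footprint, so no uniform fallback dilutes the support
        w = make_world(
            WorldConfig(n_rows=80, n_cols=80, n_settlements=8,
                        total_population=20_000, rural_fraction=0.0),
            seed=6,
        )
        pop = allocate_population(w, CONSTRAINED)
        footprint = np.zeros(w.grid.shape, bool)
        for s in w.settlements:
            for r, c in s.footprint_cells:
                footprint[r, c] = True
        nonzero = pop.values > 0
        assert (nonzero <= footprint).all()
        uniform = allocate_population(w, UNIFORM)
        assert nonzero.sum() < (uniform.values > 0).sum()

    def test_all_footprints_missed_falls_back_to_uniform(self, caplog):
        w = make_world(CFG, seed=4)
        scheme = AllocationScheme("miss", "constrained", census_unit_level=1,
                                  detection_miss_rate=0.999999)
        with caplog.at_level("WARNING"):
            pop = allocate_population(w, scheme)
        assert "spread uniformly" in caplog.text
        np.testing.assert_allclose(pop.total, w.total_population, rtol=1e-9)

    def test_coarsened_target_preserves_domain_total(self, small_world):
        target = small_world.grid.coarsen(4)
        pop = allocate_population(small_world, UNIFORM, target_grid=target)
        assert pop.grid.cell_size == 4 * small_world.grid.cell_size
        np.testing.assert_allclose(pop.total, small_world.total_population, rtol=1e-9)

    def test_misaligned_target_rejected(self, small_world):
        bad = GridSpec(20, 20, 50.0, 8000.0, 400.0)
        with pytest.raises(ValueError, match="integer coarsening"):
            allocate_population(small_world, UNIFORM, target_grid=bad)


class TestTrueCoverage:
    def test_all_households_at_facilities_is_full_coverage(self):
        # no dispersed rural population, a facility at every settlement:
        # every household sits a couple of cells from a facility
        cfg = WorldConfig(n_rows=80, n_cols=80, n_settlements=8,
                          total_population=20_000, rural_fraction=0.0)
        w = make_world(cfg, seed=7)
        friction = build_world_friction(w)
        cells = [w.grid.cell_of(s.center_x, s.center_y) for s in w.settlements]
        seeds = FacilitySeedSet(cells=[(int(r), int(c)) for r, c in cells])
        tt = least_cost_travel_time(friction, seeds)
        # 60 min walking reaches far beyond the footprint scatter (~1.5 cells)
        res = true_coverage(w, tt, 60)
        assert res.fraction == pytest.approx(1.0, abs=1e-6)

    def test_no_reachable_facility_zero_coverage(self):
        # all land cut off: facility cell reachable only by itself
        w = make_world(CFG, seed=5)
        minutes = np.full(w.grid.shape, np.nan)
        barrier = np.ones(w.grid.shape, bool)
        tt = TravelTimeGrid(minutes=minutes, barrier_mask=barrier, grid=w.grid)
        res = true_coverage(w, tt, 60)
        assert np.isnan(res.fraction)  # everyone on barrier: undefined, tallied
        assert res.pop_on_barrier == w.total_population

    def test_manual_enumeration_on_tiny_world(self):
        # 10 households placed by hand via a synthetic world's own grid:
        # travel time below threshold for exactly 6 of them
        grid = GridSpec(4, 4, 0.0, 400.0, 100.0)
        minutes = np.full((4, 4), 100.0)
        minutes[:2] = 10.0  # northern half within a 30-min threshold
        tt = TravelTimeGrid(minutes=minutes, barrier_mask=np.zeros((4, 4), bool), grid=grid)

        class Tiny:
            pass

        w = Tiny()
        w.grid = grid
        xs = [50, 150, 250, 350, 50, 150, 250, 350, 50, 150]
        ys = [350, 350, 350, 350, 250, 250, 150, 150, 50, 50]  # 6 in north half
        w.households_xy = np.column_stack([xs, ys]).astype(float)
        w._tally = None
        w.household_tally = lambda: (
            np.histogram2d(
                (grid.origin_y - w.households_xy[:, 1]) // 100,
                w.households_xy[:, 0] // 100,
                bins=[np.arange(5), np.arange(5)],
            )[0]
        )
        res = true_coverage(w, tt, 30)
        assert res.fraction == pytest.approx(6 / 10)

    def test_mismatched_grid_rejected(self, small_world):
        other = GridSpec(10, 10, 0.0, 1000.0, 100.0)
        tt = TravelTimeGrid(minutes=np.zeros((10, 10)),
                            barrier_mask=np.zeros((10, 10), bool), grid=other)
        with pytest.raises(ValueError):
            true_coverage(small_world, tt, 30)
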