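"""Friction-surface construction: rasterization, merging, scenario, crossing times."""

import numpy as np
import pytest
from shapely.geometry import LineString, Polygon

from geoaccess import GridSpec, ScenarioRow, ScenarioTable
from geoaccess.friction import (
    NO_CLASS,
    PROV_BARRIER,
    PROV_LANDCOVER,
    PROV_ROAD,
    build_friction,
    merge_layers,
    rasterize_barriers,
    rasterize_lines,
    resolve_scenario,
)
from geoaccess.grid import CRSMismatchError
from geoaccess.scenario import ScenarioError
from geoaccess.vectors import Feature, FeatureCollection


def fc(geoms_attrs, crs="local:metric"):
    return FeatureCollection([Feature(g, a) for g, a in geoms_attrs], crs_id=crs)


SPEEDS = {10: 80.0, 11: 50.0, 12: 30.0}


class TestRasterizeLines:
    def test_horizontal_line_sets_whole_row(self):
        grid = GridSpec(1, 5, 0.0, 1.0, 1.0)
        lines = fc([(LineString([(0.1, 0.5), (4.9, 0.5)]), {"class_code": 10})])
        out = rasterize_lines(lines, grid, SPEEDS)
        assert (out[0] == 10).all()

    def test_diagonal_all_touched(self):
        # corner-to-corner diagonal of a 3x3 grid: the three diagonal cells
        # must be set; cells touched only at corners may also be set
        grid = GridSpec(3, 3, 0.0, 3.0, 1.0)
        lines = fc([(LineString([(0, 3), (3, 0)]), {"class_code": 10})])
        out = rasterize_lines(lines, grid, SPEEDS)
        hit = set(zip(*np.nonzero(out == 10)))
        assert {(0, 0), (1, 1), (2, 2)} <= hit
        assert hit <= {(0, 0), (1, 1), (2, 2), (0, 1), (1, 0), (1, 2), (2, 1)}

    def test_faster_class_wins_in_shared_cell(self):
        grid = GridSpec(3, 3, 0.0, 3.0, 1.0)
        lines = fc(
            [
                (LineString([(0, 1.5), (3, 1.5)]), {"class_code": 12}),  # tertiary
                (LineString([(1.5, 0), (1.5, 3)]), {"class_code": 10}),  # primary
            ]
        )
        out = rasterize_lines(lines, grid, SPEEDS)
        assert out[1, 1] == 10  # crossing cell coded primary (80 > 30 km/h)
        assert out[1, 0] == 12 and out[0, 1] == 10

    def test_crs_mismatch_refused(self):
        grid = GridSpec(3, 3, 0.0, 3.0, 1.0, crs_id="EPSG:32633")
        lines = fc([(LineString([(0, 0), (1, 1)]), {"class_code": 10})], crs="EPSG:32734")
        with pytest.raises(CRSMismatchError):
            rasterize_lines(lines, grid, SPEEDS)


class TestRasterizeBarriers:
    def test_polygon_covers_2x2_block(self):
        grid = GridSpec(4, 4, 0.0, 4.0, 1.0)
        water = fc([(Polygon([(1, 1), (3, 1), (3, 3), (1, 3)]), {})])
        mask = rasterize_barriers(None, water, grid)
        assert mask.sum() == 4
        assert mask[1:3, 1:3].all()

    def test_river_line_all_touched_cells(self):
        # vertical river through column 2 of a 6-row grid: 6 cells, enumerated
        grid = GridSpec(6, 6, 0.0, 6.0, 1.0)
        rivers = fc([(LineString([(2.5, 6), (2.5, 0)]), {})])
        mask = rasterize_barriers(rivers, None, grid)
        assert set(zip(*np.nonzero(mask))) == {(r, 2) for r in range(6)}

    def test_empty_layers_all_false(self):
        grid = GridSpec(3, 3, 0.0, 3.0, 1.0)
        mask = rasterize_barriers(fc([]), fc([]), grid)
        assert not mask.any()


class TestMergeLayers:
    grid = GridSpec(1, 3, 0.0, 1.0, 1.0)
    forest = np.full((1, 3), 2)

    def test_priority_road_over_barrier_over_landcover(self):
        roads = np.array([[10, NO_CLASS, NO_CLASS]])
        barrier = np.array([[True, True, False]])
        merged = merge_layers(self.forest, roads, barrier, self.grid, barrier_class=200)
        assert merged.classes.tolist() == [[10, 200, 2]]
        assert merged.provenance.tolist() == [[PROV_ROAD, PROV_BARRIER, PROV_LANDCOVER]]

    def test_incomplete_landcover_rejected(self):
        bad = np.array([[2, -1, 2]])
        with pytest.raises(ValueError, match="incomplete"):
            merge_layers(bad, np.full((1, 3), NO_CLASS), np.zeros((1, 3), bool),
                         self.grid, barrier_class=200)


class TestResolveScenario:
    base = ScenarioTable([ScenarioRow(1, "open", "offroad", 5.0)])

    def test_missing_road_class_filled_from_fallback(self):
        out = resolve_scenario(self.base, [1, 13], {13: 70.0})
        assert out.speed(13) == 70.0

    def test_fully_specified_returned_unchanged(self):
        assert resolve_scenario(self.base, [1], {}) is self.base

    def test_unknown_class_error_names_it(self):
        with pytest.raises(ScenarioError, match="999"):
            resolve_scenario(self.base, [1, 999], {13: 70.0})


class TestBuildFriction:
    def make(self, classes, scenario, cell=100.0):
        grid = GridSpec(*classes.shape, 0.0, classes.shape[0] * cell, cell)
        merged = merge_layers(classes, np.full(classes.shape, NO_CLASS),
                              np.zeros(classes.shape, bool), grid, barrier_class=200)
        return build_friction(merged, scenario)

    scenario = ScenarioTable(
        [
            ScenarioRow(10, "primary", "road", 80.0),
            ScenarioRow(1, "walk", "offroad", 5.0),
            ScenarioRow(200, "water", "barrier", None),
        ]
    )

    def test_crossing_times(self):
        # 100 m at 80 km/h -> 0.075 min; 100 m at 5 km/h -> 1.2 min
        fricgrid = self.make(np.array([[10, 1]]), self.scenario)
        np.testing.assert_allclose(fricgrid.minutes, [[0.075, 1.2]])

    def test_barrier_cells_masked_without_finite_time(self):
        fricgrid = self.make(np.array([[10, 200]]), self.scenario)
        assert fricgrid.barrier_mask.tolist() == [[False, True]]
        assert np.isnan(fricgrid.minutes[0, 1])

    def test_speed_monotonicity(self):
        slow = self.make(np.array([[10, 1]]), self.scenario)
        faster = ScenarioTable(
            [
                ScenarioRow(10, "primary", "road", 100.0),
                ScenarioRow(1, "walk", "offroad", 6.0),
                ScenarioRow(200, "water", "barrier", None),
            ]
        )
        fast = self.make(np.array([[10, 1]]), faster)
        assert (fast.minutes <= slow.minutes).all()

    def test_cell_size_scaling(self):
        f100 = self.make(np.array([[10, 1]]), self.scenario, cell=100.0)
        f200 = self.make(np.array([[10, 1]]), self.scenario, cell=200.0)
        np.testing.assert_allclose(f200.minutes, 2 * f100.minutes)

    def test_bridge_property_roads_never_barriers(self):
        grid = GridSpec(1, 2, 0.0, 100.0, 100.0)
        merged = merge_layers(
            np.array([[1, 1]]), np.array([[10, NO_CLASS]]),
            np.array([[True, True]]), grid, barrier_class=200,
        )
        fricgrid = build_friction(merged, self.scenario)
        assert not fricgrid.barrier_mask[0, 0] and fricgrid.barrier_mask[0, 1]
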