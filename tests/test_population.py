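"""Harmonization mass preservation, centroid points, and point classification."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from geoaccess import GridSpec, classify_points, harmonize, to_points
from geoaccess.grid import CRSMismatchError
from geoaccess.population import PopulationGrid, STATUS_BARRIER, STATUS_OK, \
    STATUS_OUT_OF_REGION, STATUS_UNREACHABLE
from geoaccess.travel import TravelTimeGrid
from geoaccess.vectors import Feature, FeatureCollection


def units_fc(boxes_ids, crs="local:metric"):
    return FeatureCollection(
        [Feature(box(*b), {"admin_id": i}) for b, i in boxes_ids], crs_id=crs
    )


GRID4 = GridSpec(4, 4, 0.0, 400.0, 100.0)
# two level-2 units splitting the 400x400 m domain west/east
UNITS = units_fc([((0, 0, 200, 400), "W"), ((200, 0, 400, 400), "E")])


class TestHarmonize:
    def test_lossless_input_scale_factor_one(self):
        values = np.arange(16, dtype=float).reshape(4, 4)
        pop, report = harmonize(PopulationGrid(values, GRID4, "p"), UNITS)
        np.testing.assert_allclose(np.nan_to_num(pop.values), values)
        assert all(f == pytest.approx(1.0) for f in report.factors.values())

    def test_per_unit_rescale_restores_original_totals(self):
        # the processed raster retained only 987.3 of the unit's original 1000
        values = np.zeros((4, 4))
        values[:, :2] = 987.3 / 8
        pop, report = harmonize(
            PopulationGrid(values, GRID4, "p"), UNITS,
            original_totals={"W": 1000.0, "E": 0.0},
        )
        west = pop.values[:, :2]
        assert west.sum() == pytest.approx(1000.0, rel=1e-12)
        assert report.factors["W"] == pytest.approx(1000.0 / 987.3)
        np.testing.assert_allclose(west, west[0, 0])  # proportional, pattern kept

    def test_unit_with_all_population_lost_respread_uniformly(self, caplog):
        values = np.zeros((4, 4))
        values[:, :2] = 10.0
        with caplog.at_level("WARNING"):
            pop, report = harmonize(
                PopulationGrid(values, GRID4, "p"), UNITS,
                original_totals={"W": 80.0, "E": 640.0},
            )
        assert report.respread_units == ["E"]
        np.testing.assert_allclose(pop.values[:, 2:], 640.0 / 8)
        assert "respread" in caplog.text

    def test_disjoint_region_fails(self):
        far = units_fc([((5000, 5000, 6000, 6000), "X")])
        with pytest.raises(ValueError, match="disjoint"):
            harmonize(PopulationGrid(np.ones((4, 4)), GRID4, "p"), far)

    def test_mixed_crs_refused(self):
        other = units_fc([((0, 0, 400, 400), "W")], crs="EPSG:32733")
        with pytest.raises(CRSMismatchError):
            harmonize(PopulationGrid(np.ones((4, 4)), GRID4, "p"), other)

    def test_reharmonizing_changes_nothing(self):
        rng = np.random.default_rng(8)
        values = rng.uniform(0, 50, (4, 4))
        once, _ = harmonize(PopulationGrid(values, GRID4, "p"), UNITS)
        twice, _ = harmonize(once, UNITS)
        np.testing.assert_allclose(np.nan_to_num(twice.values),
                                   np.nan_to_num(once.values), rtol=1e-12)


class TestToPoints:
    def test_small_grid_example(self):
        grid = GridSpec(2, 2, 0.0, 200.0, 100.0)
        pts = to_points(PopulationGrid(np.array([[0.0, 5.0], [2.0, 0.0]]), grid, "d"))
        assert len(pts) == 2
        assert pts["count"].sum() == 7.0
        top_right = pts[pts["count"] == 5.0].iloc[0]
        assert (top_right.x, top_right.y) == (150.0, 150.0)

    def test_all_zero_grid_empty_points(self):
        grid = GridSpec(2, 2, 0.0, 200.0, 100.0)
        assert to_points(PopulationGrid(np.zeros((2, 2)), grid, "d")).empty

    def test_random_grid_count_and_total_preserved(self):
        rng = np.random.default_rng(9)
        values = np.where(rng.random((25, 40)) < 0.5, 0.0, rng.uniform(1, 9, (25, 40)))
        grid = GridSpec(25, 40, 0.0, 2500.0, 100.0)
        pts = to_points(PopulationGrid(values, grid, "d"))
        assert len(pts) == int((values > 0).sum())
        assert pts["count"].sum() == pytest.approx(values.sum(), rel=1e-12)


def make_travel(minutes, barrier=None):
    minutes = np.asarray(minutes, float)
    barrier = np.zeros(minutes.shape, bool) if barrier is None else barrier
    grid = GridSpec(*minutes.shape, 0.0, minutes.shape[0] * 100.0, 100.0)
    return TravelTimeGrid(minutes=np.where(barrier, np.nan, minutes),
                          barrier_mask=barrier, grid=grid)


class TestClassifyPoints:
    admin = {1: units_fc([((0, 0, 400, 400), "A1")]), 2: UNITS}

    def test_travel_time_and_admin_annotation(self):
        tt = make_travel(np.full((4, 4), 42.0))
        pts = pd.DataFrame({"x": [50.0], "y": [350.0], "count": [3.0], "dataset": ["d"]})
        out = classify_points(pts, tt, self.admin, levels=(1, 2))
        assert out.loc[0, "travel_time_min"] == 42.0
        assert out.loc[0, "admin1_id"] == "A1" and out.loc[0, "admin2_id"] == "W"
        assert out.loc[0, "status"] == STATUS_OK

    def test_point_on_barrier_retained_with_marker(self):
        barrier = np.zeros((4, 4), bool)
        barrier[0, 0] = True
        tt = make_travel(np.full((4, 4), 10.0), barrier)
        pts = pd.DataFrame({"x": [50.0], "y": [350.0], "count": [2.0], "dataset": ["d"]})
        out = classify_points(pts, tt, self.admin)
        assert out.loc[0, "status"] == STATUS_BARRIER
        assert len(out) == 1  # kept for the barrier tally

    def test_unreachable_and_outside_statuses(self):
        minutes = np.full((4, 4), np.inf)
        tt = make_travel(minutes)
        pts = pd.DataFrame(
            {"x": [50.0, 5000.0], "y": [350.0, 350.0], "count": [1.0, 1.0],
             "dataset": ["d", "d"]}
        )
        out = classify_points(pts, tt, self.admin)
        assert out["status"].tolist() == [STATUS_UNREACHABLE, STATUS_OUT_OF_REGION]

    def test_boundary_point_single_deterministic_assignment(self):
        # x=200 lies exactly on the W/E unit edge: covered by both polygons,
        # assigned to the first in stable id order
        tt = make_travel(np.full((4, 4), 1.0))
        pts = pd.DataFrame({"x": [200.0], "y": [200.0], "count": [1.0], "dataset": ["d"]})
        out = classify_points(pts, tt, self.admin)
        assert out.loc[0, "admin2_id"] == "E"  # 'E' < 'W' in id order

    def test_classification_is_total(self, small_world):
        from geoaccess import run_world

        res = run_world(small_world, thresholds_min=(30,))
        statuses = set(res["points"]["status"].unique())
        assert statuses <= {STATUS_OK, STATUS_BARRIER, STATUS_UNREACHABLE,
                            STATUS_OUT_OF_REGION}
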