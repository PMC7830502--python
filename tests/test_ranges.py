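import numpy as np
import pytest
from shapely.geometry import MultiPoint, box

from rangeshift.exceptions import GridAlignmentError
from rangeshift.grids import GridDefinition, RasterGrid
from rangeshift.ranges import (
    AOOEstimate,
    alpha_hull,
    aoo_change_percent,
    apply_dispersal,
    buffer_eoo,
    compute_aoo,
    default_alpha,
    make_change_map,
    mask_by_landcover,
    mask_by_polygon,
)

GRID = GridDefinition(10, 10, 0.0, 10.0, 1.0, 1.0)


def _binary(cells) -> RasterGrid:
    values = np.zeros((10, 10))
    for r, c in cells:
        values[r, c] = 1.0
    return RasterGrid(values, GRID)


class TestAlphaHull:
    points = np.array([
        [0.0, 0.0], [1.0, 0.1], [2.0, 0.0], [0.1, 1.0], [1.0, 1.1],
        [2.1, 1.0], [0.5, 0.5], [1.5, 0.6],
    ])

    def test_huge_alpha_equals_convex_hull(self):
        hull = alpha_hull(self.points, alpha=1e9)
        convex = MultiPoint(self.points).convex_hull
        assert hull.symmetric_difference(convex).area < 1e-9

    def test_area_never_exceeds_convex_hull(self):
        rng = np.random.default_rng(0)
        for seed in range(5):
            pts = np.random.default_rng(seed).random((20, 2)) * 5
            convex_area = MultiPoint(pts).convex_hull.area
            for alpha in (0.5, 1.0, 3.0):
                assert alpha_hull(pts, alpha).area <= convex_area + 1e-9

    def test_disjunct_clusters_yield_multipart_hull(self):
        rng = np.random.default_rng(1)
        a = rng.random((15, 2))
        b = rng.random((15, 2)) + [50.0, 0.0]
        hull = alpha_hull(np.vstack([a, b]), alpha=2.0)
        assert hull.geom_type == "MultiPolygon"
        assert len(hull.geoms) == 2

    def test_collinear_points_fall_back_to_buffer(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [3.0, 0.0]])
        with pytest.warns(UserWarning, match="degenerate"):
            hull = alpha_hull(pts, alpha=0.5)
        assert hull.area > 0
        assert all(hull.contains_properly(MultiPoint([p])) for p in pts)

    def test_alpha_must_be_positive(self):
        with pytest.raises(ValueError):
            alpha_hull(self.points, alpha=0.0)

    def test_default_alpha_positive(self):
        assert default_alpha(self.points) > 0


class TestBufferEoo:
    def test_zero_buffer_is_identity(self):
        square = box(0, 0, 1, 1)
        eoo = buffer_eoo(square, 0.0)
        assert eoo.geometry.equals(square)

    def test_unit_square_buffer_closed_form(self):
        # Minkowski sum of unit square and radius-0.1 disc:
        # 1 + 4*(1*0.1) + pi*0.1^2
        eoo = buffer_eoo(box(0, 0, 1, 1), 0.1)
        expected = 1.0 + 4 * 0.1 + np.pi * 0.01
        assert eoo.geometry.area == pytest.approx(expected, rel=1e-3)

    def test_points_strictly_inside_buffered_hull(self):
        rng = np.random.default_rng(2)
        pts = rng.random((12, 2)) * 3
        hull = alpha_hull(pts, alpha=default_alpha(pts))
        eoo = buffer_eoo(hull, 0.1)
        assert all(eoo.geometry.contains_properly(MultiPoint([p])) for p in pts)

    def test_negative_buffer_rejected(self):
        with pytest.raises(ValueError):
            buffer_eoo(box(0, 0, 1, 1), -0.1)

    def test_geojson_round_trip(self, tmp_path):
        import json

        eoo = buffer_eoo(box(0, 0, 1, 1), 0.1)
        path = eoo.write_geojson(tmp_path / "eoo.geojson")
        data = json.loads(path.read_text())
        assert data["features"][0]["geometry"]["type"] == "Polygon"
        assert data["features"][0]["properties"]["buffer_deg"] == 0.1


class TestMasking:
    def test_full_cover_polygon_is_identity(self):
        binary = _binary([(1, 1), (5, 5), (9, 9)])
        out = mask_by_polygon(binary, box(-1, -1, 11, 11))
        np.testing.assert_array_equal(out.values, binary.values)

    def test_disjoint_polygon_zeroes_everything(self):
        binary = _binary([(1, 1), (5, 5)])
        with pytest.warns(UserWarning):
            out = mask_by_polygon(binary, box(100, 100, 101, 101))
        assert np.nansum(out.values) == 0

    def test_polygon_mask_is_monotone_and_idempotent(self):
        binary = _binary([(r, c) for r in range(10) for c in range(0, 10, 2)])
        poly = box(0, 0, 5, 5)
        once = mask_by_polygon(binary, poly)
        assert np.nansum(once.values) <= np.nansum(binary.values)
        twice = mask_by_polygon(once, poly)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_landcover_allow_all_identity(self):
        binary = _binary([(2, 3), (4, 4)])
        landcover = RasterGrid(np.full((10, 10), 1.0), GRID)
        out = mask_by_landcover(binary, landcover, {1})
        np.testing.assert_array_equal(out.values, binary.values)

    def test_landcover_allow_none_zeroes(self):
        binary = _binary([(2, 3), (4, 4)])
        landcover = RasterGrid(np.full((10, 10), 1.0), GRID)
        out = mask_by_landcover(binary, landcover, set())
        assert np.nansum(out.values) == 0

    def test_landcover_mask_idempotent(self):
        rng = np.random.default_rng(3)
        binary = RasterGrid((rng.random((10, 10)) > 0.5).astype(float), GRID)
        landcover = RasterGrid(rng.choice([1.0, 2.0, 3.0], (10, 10)), GRID)
        once = mask_by_landcover(binary, landcover, {1, 2})
        twice = mask_by_landcover(once, landcover, {1, 2})
        np.testing.assert_array_equal(once.values, twice.values)

    def test_mask_order_commutes(self):
        rng = np.random.default_rng(4)
        binary = RasterGrid((rng.random((10, 10)) > 0.4).astype(float), GRID)
        landcover = RasterGrid(rng.choice([1.0, 2.0], (10, 10)), GRID)
        poly = box(1, 1, 8, 8)
        a = mask_by_polygon(mask_by_landcover(binary, landcover, {1}), poly)
        b = mask_by_landcover(mask_by_polygon(binary, poly), landcover, {1})
        np.testing.assert_array_equal(a.values, b.values)

    def test_misaligned_landcover_errors(self):
        binary = _binary([(0, 0)])
        other = GridDefinition(10, 10, 50.0, 10.0, 1.0, 1.0)
        landcover = RasterGrid(np.ones((10, 10)), other)
        with pytest.raises(GridAlignmentError):
            mask_by_landcover(binary, landcover, {1})


class TestAoo:
    def test_seven_cells_is_28_km2(self):
        binary = _binary([(0, 0), (1, 1), (2, 2), (3, 3), (4, 4), (5, 5), (6, 6)])
        aoo = compute_aoo(binary)
        assert aoo.cell_count == 7
        assert aoo.area_km2 == 28.0

    def test_empty_map_is_zero(self):
        aoo = compute_aoo(_binary([]))
        assert aoo.cell_count == 0 and aoo.area_km2 == 0.0

    def test_matches_naive_cell_loop(self):
        rng = np.random.default_rng(5)
        values = (rng.random((10, 10)) > 0.6).astype(float)
        values[0, :3] = np.nan
        binary = RasterGrid(values, GRID)
        naive = sum(
            1
            for r in range(10)
            for c in range(10)
            if np.isfinite(values[r, c]) and values[r, c] == 1
        )
        assert compute_aoo(binary).cell_count == naive


class TestChangeMap:
    def test_identical_maps_no_loss_no_gain(self):
        binary = _binary([(1, 1), (2, 2)])
        change = make_change_map(binary, binary)
        counts = change.counts()
        assert counts["loss"] == 0 and counts["gain"] == 0 and counts["stable"] == 2

    def test_empty_future_is_total_loss(self):
        current = _binary([(1, 1), (2, 2), (3, 3)])
        change = make_change_map(current, _binary([]))
        assert change.counts()["loss"] == 3
        assert change.counts()["stable"] == 0

    def test_classes_partition_valid_cells(self):
        rng = np.random.default_rng(6)
        cur = RasterGrid((rng.random((10, 10)) > 0.5).astype(float), GRID)
        fut = RasterGrid((rng.random((10, 10)) > 0.5).astype(float), GRID)
        counts = make_change_map(cur, fut).counts()
        assert sum(counts.values()) == 100

    def test_misaligned_errors(self):
        other = GridDefinition(10, 10, 50.0, 10.0, 1.0, 1.0)
        with pytest.raises(GridAlignmentError):
            make_change_map(_binary([(0, 0)]), RasterGrid(np.zeros((10, 10)), other))


class TestDispersal:
    def test_set_algebra_of_scenarios(self):
        # current {A, B}, future {B, C}: none -> {B}; full -> {B, C}
        current = _binary([(0, 0), (1, 1)])  # A, B
        future = _binary([(1, 1), (2, 2)])  # B, C
        change = make_change_map(current, future)
        none = apply_dispersal(change, "none").future_binary()
        full = apply_dispersal(change, "full").future_binary()
        assert np.nansum(none.values) == 1 and none.values[1, 1] == 1
        assert np.nansum(full.values) == 2 and full.values[2, 2] == 1

    def test_no_dispersal_aoo_never_exceeds_full(self):
        rng = np.random.default_rng(7)
        for seed in range(5):
            r = np.random.default_rng(seed)
            cur = RasterGrid((r.random((10, 10)) > 0.5).astype(float), GRID)
            fut = RasterGrid((r.random((10, 10)) > 0.5).astype(float), GRID)
            change = make_change_map(cur, fut)
            none_aoo = compute_aoo(apply_dispersal(change, "none").future_binary())
            full_aoo = compute_aoo(apply_dispersal(change, "full").future_binary())
            assert none_aoo.cell_count <= full_aoo.cell_count

    def test_no_gain_cells_makes_none_identity(self):
        current = _binary([(1, 1), (2, 2)])
        future = _binary([(1, 1)])
        change = make_change_map(current, future)
        out = apply_dispersal(change, "none")
        np.testing.assert_array_equal(out.raster.values, change.raster.values)

    def test_unknown_scenario_errors(self):
        change = make_change_map(_binary([(0, 0)]), _binary([]))
        with pytest.raises(ValueError):
            apply_dispersal(change, "partial")


class TestChangePercent:
    def test_total_loss(self):
        assert aoo_change_percent(
            AOOEstimate(50), AOOEstimate(0)
        ) == pytest.approx(-100.0)

    def test_26_percent_gain(self):
        assert aoo_change_percent(
            AOOEstimate(50), AOOEstimate(63)
        ) == pytest.approx(26.0)

    def test_no_change(self):
        assert aoo_change_percent(AOOEstimate(17), AOOEstimate(17)) == 0.0

    def test_zero_current_errors(self):
        with pytest.raises(ValueError):
            aoo_change_percent(AOOEstimate(0), AOOEstimate(10))
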