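"""Grid data model, IO round-trips, aggregation, terrain and landscape metrics."""

import numpy as np
import pytest
import shapely
from shapely.geometry import LineString, Point, box

from ecoscape.grids import (Grid, VectorLayer, aggregate, aggregate_circular,
                            euclidean_distance, landscape_diversity,
                            landscape_fragmentation, read_grid, read_vector,
                            slope_aspect, write_grid, write_vector)

from conftest import grid_of


class TestIO:
    def test_roundtrip_preserves_values_and_georeferencing(self, tmp_path):
        g = Grid(np.arange(1, 10, dtype=float).reshape(3, 3),
                 origin_x=1000.0, origin_y=2000.0, cell_size=25.0, nodata=-1.0)
        path = tmp_path / "g.tif"
        write_grid(g, path)
        g2 = read_grid(path)
        assert np.array_equal(g2.values, g.values)
        assert (g2.origin_x, g2.origin_y, g2.cell_size) == (1000.0, 2000.0, 25.0)
        assert g2.nodata == -1.0

    def test_second_write_is_byte_identical(self, tmp_path):
        g = grid_of(np.random.default_rng(0).random((5, 7)))
        write_grid(g, tmp_path / "a.tif")
        write_grid(read_grid(tmp_path / "a.tif"), tmp_path / "b.tif")
        assert (tmp_path / "a.tif").read_bytes() == (tmp_path / "b.tif").read_bytes()

    def test_nodata_cells_excluded_from_statistics(self, tmp_path):
        vals = np.array([[1.0, -9999.0], [3.0, 5.0]])
        g = Grid(vals, nodata=-9999.0)
        write_grid(g, tmp_path / "g.tif")
        g2 = read_grid(tmp_path / "g.tif")
        data = g2.filled()
        assert np.nanmin(data) == 1.0 and np.nanmax(data) == 5.0

    def test_missing_file_rejected(self, tmp_path):
        with pytest.raises((FileNotFoundError, ValueError)):
            read_grid(tmp_path / "nope.tif")

    def test_vector_roundtrip(self, tmp_path):
        layer = VectorLayer([LineString([(0, 0), (10, -5)]), box(0, -10, 5, -5)],
                            [{"a": 1}, {"a": 2}])
        write_vector(layer, tmp_path / "v.geojson")
        back = read_vector(tmp_path / "v.geojson")
        assert len(back) == 2
        assert back.attributes[1]["a"] == 2
        assert back.geometries[0].equals(layer.geometries[0])


class TestAggregate:
    def test_factor_one_mean_is_identity(self):
        g = grid_of(np.random.default_rng(1).random((6, 5)))
        out = aggregate(g, 1, "mean")
        assert np.array_equal(out.values, g.values)

    def test_hand_mean(self):
        out = aggregate(grid_of([[1, 3], [5, 7]]), 2, "mean")
        assert out.values.shape == (1, 1)
        assert out.values[0, 0] == 4.0
        assert out.cell_size == 50.0

    def test_all_ones_stay_ones(self):
        out = aggregate(grid_of(np.ones((4, 4))), 2, "mean")
        assert np.all(out.values == 1.0)

    def test_nodata_block_and_partial_blocks(self):
        vals = np.array([[1.0, np.nan, 2.0], [3.0, 4.0, 6.0]])
        g = Grid.from_nan(vals, grid_of(np.zeros((2, 3))))
        out = aggregate(g, 2, "mean")
        # first block mean of {1,3,4}; trailing partial block mean of {2,6}
        assert np.isclose(out.values[0, 0], 8 / 3)
        assert np.isclose(out.values[0, 1], 4.0)

    def test_all_nodata_block_is_nodata(self):
        vals = np.full((2, 2), np.nan)
        vals[:, 1] = 5.0
        g = Grid.from_nan(vals, grid_of(np.zeros((2, 2))))
        out = aggregate(g, 2, "mean")  # single block keeps the valid cells
        assert np.isclose(out.values[0, 0], 5.0)
        g2 = Grid.from_nan(np.full((2, 2), np.nan), grid_of(np.zeros((2, 2))))
        assert not aggregate(g2, 2, "mean").mask().any()

    def test_majority(self):
        out = aggregate(grid_of([[1, 1], [2, 1]]), 2, "majority")
        assert out.values[0, 0] == 1.0

    def test_bad_factor(self):
        with pytest.raises(ValueError):
            aggregate(grid_of(np.ones((2, 2))), 0, "mean")

    def test_circular_mean_wraps(self):
        g = grid_of([[350.0, 10.0], [350.0, 10.0]])
        out = aggregate_circular(g, 2)
        assert np.isclose(out.values[0, 0] % 360.0, 0.0, atol=1e-9)


class TestTerrain:
    def test_constant_dem_flat(self):
        s, a = slope_aspect(grid_of(np.full((5, 5), 100.0), cell_size=10))
        assert np.allclose(s.filled()[1:-1, 1:-1], 0.0)
        assert not a.mask()[1:-1, 1:-1].any()  # aspect undefined when flat

    def test_tilted_plane_matches_analytic_gradient(self):
        # z = x with 1 m cells -> 45 degree slope everywhere in the interior
        xs = np.tile(np.arange(20, dtype=float), (20, 1))
        s, a = slope_aspect(Grid(xs, cell_size=1.0))
        assert np.allclose(s.filled()[1:-1, 1:-1], 45.0, atol=1e-6)
        # downslope faces west (270) since z rises eastward
        assert np.allclose(a.filled()[1:-1, 1:-1], 270.0, atol=1e-6)

    def test_rising_northward_faces_south(self):
        z = -np.tile(np.arange(20, dtype=float)[:, None], (1, 20))
        s, a = slope_aspect(Grid(z, cell_size=1.0))
        assert np.allclose(a.filled()[1:-1, 1:-1], 180.0, atol=1e-6)

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError):
            slope_aspect(grid_of(np.ones((2, 2))))


class TestDistance:
    def test_vertical_line_grows_linearly(self):
        g = grid_of(np.zeros((5, 5)), cell_size=10.0)
        # line through the center-column cell centers (x = 25)
        layer = VectorLayer([LineString([(25, 0), (25, -50)])])
        d = euclidean_distance(layer, g)
        col_dist = np.abs((np.arange(5) + 0.5) * 10.0 - 25.0)
        assert np.allclose(d.values, np.tile(col_dist, (5, 1)))

    def test_cover_all_zero(self):
        g = grid_of(np.zeros((4, 4)), cell_size=10.0)
        layer = VectorLayer([box(-1, -41, 41, 1)])
        assert np.allclose(euclidean_distance(layer, g).values, 0.0)

    def test_point_target_four_neighbors(self):
        g = grid_of(np.zeros((3, 3)), cell_size=10.0)
        layer = VectorLayer([Point(15.0, -15.0)])  # center cell center
        d = euclidean_distance(layer, g).values
        assert d[1, 1] == 0.0
        assert np.allclose([d[0, 1], d[2, 1], d[1, 0], d[1, 2]], 10.0)

    def test_triangle_inequality(self, rng):
        g = grid_of(np.zeros((6, 6)), cell_size=5.0)
        layer = VectorLayer([Point(rng.uniform(0, 30), -rng.uniform(0, 30))])
        d = euclidean_distance(layer, g).values
        xx, yy = g.cell_centers()
        i, j = (1, 2), (4, 5)
        dij = np.hypot(xx[i] - xx[j], yy[i] - yy[j])
        assert d[i] <= d[j] + dij + 1e-9

    def test_empty_layer_rejected(self):
        with pytest.raises(ValueError):
            euclidean_distance(VectorLayer([]), grid_of(np.zeros((3, 3))))


class TestLandscapeMetrics:
    def test_single_class_window(self):
        h = landscape_diversity(grid_of(np.ones((7, 7))), 3)
        f = landscape_fragmentation(grid_of(np.ones((7, 7))), 3)
        assert np.allclose(h.filled(), 0.0)
        assert np.allclose(f.filled(), 0.0)

    def test_two_equal_classes_ln2(self):
        stripes = np.tile([1.0, 2.0], (6, 3))
        h = landscape_diversity(grid_of(stripes), 3)
        # interior windows hold 6+3 or 3+6 cells; a window with equal splits:
        half = np.zeros((6, 6))
        half[:, 3:] = 1.0
        hh = landscape_diversity(grid_of(half), 3)
        # column 3 windows: 3 cells of class 0, 6 of class 1? col 2..4 mix
        vals = hh.filled()
        equal = landscape_diversity(grid_of(np.tile([0.0, 1.0], (9, 5))[:, :9]), 3)
        assert np.nanmax(equal.filled()) <= np.log(2) + 1e-9

    def test_k_classes_reach_ln_k(self):
        for k in (2, 3):
            arr = np.tile(np.arange(k, dtype=float), (9, 9 // k + 1))[:9, :9]
            h = landscape_diversity(grid_of(arr), 2 * k - 1)
            assert np.nanmax(h.filled()) <= np.log(k) + 1e-9
        # exact ln k window: 3x3 with 3 classes x 3 cells each
        arr = np.repeat(np.arange(3.0), 3).reshape(3, 3).T
        arr = np.tile(arr, (3, 3))
        h = landscape_diversity(grid_of(arr), 3)
        assert np.isclose(np.nanmax(h.filled()), np.log(3), atol=1e-9)

    def test_checkerboard_fragmentation_is_one(self):
        cb = (np.indices((9, 9)).sum(axis=0) % 2).astype(float)
        f = landscape_fragmentation(grid_of(cb), 3)
        assert np.allclose(f.filled(), 1.0)

    def test_two_half_windows_strictly_between(self):
        half = np.zeros((9, 9))
        half[:, 4:] = 1.0
        f = landscape_fragmentation(grid_of(half), 3).filled()
        boundary = f[4, 4]
        assert 0.0 < boundary < 1.0

    def test_relabeling_invariance(self, rng):
        arr = rng.integers(0, 4, (10, 10)).astype(float)
        relab = arr * 7.0 + 3.0  # injective relabeling
        for fn in (landscape_diversity, landscape_fragmentation):
            a = fn(grid_of(arr), 5).filled()
            b = fn(grid_of(relab), 5).filled()
            assert np.allclose(a, b, equal_nan=True)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            landscape_diversity(grid_of(np.ones((5, 5))), 4)
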