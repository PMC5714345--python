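"""Getis-Ord Gi*, hotspot classes, overlaps, corrected correlation."""

import numpy as np
import pytest
from scipy import ndimage

from ecoscape.congruence import (COLD, HOT, NODATA_CLASS, NS, HotspotGrid,
                                 SpatialWeights, classify_hotspots,
                                 congruence_report, dutilleul_correlation,
                                 gi_star, overlap_percent)
from ecoscape.grids import Grid


def km_grid(vals):
    return Grid(np.asarray(vals, dtype=float), cell_size=1000.0)


def gi_star_bruteforce(grid, band=3000.0):
    """Independent double-loop evaluation of the Gi* formula."""
    vals = grid.filled()
    valid = np.isfinite(vals)
    n = valid.sum()
    xbar = vals[valid].mean()
    s = vals[valid].std(ddof=0)
    xx, yy = grid.cell_centers()
    out = np.full(vals.shape, np.nan)
    for r in range(vals.shape[0]):
        for c in range(vals.shape[1]):
            if not valid[r, c]:
                continue
            d = np.hypot(xx - xx[r, c], yy - yy[r, c])
            w = ((d <= band + 1e-9) & valid).astype(float)
            wi = w.sum()
            ci = (w**2).sum()
            denom = s * np.sqrt((n * ci - wi**2) / (n - 1))
            if denom > 0:
                wx = (w * np.where(valid, vals, 0.0)).sum()
                out[r, c] = (wx - xbar * wi) / denom
    return out


class TestGiStar:
    def test_matches_bruteforce_oracle(self, rng):
        g = km_grid(rng.random((10, 10)) * 40)
        z = gi_star(g, SpatialWeights(band_distance=3000.0)).z.filled()
        zb = gi_star_bruteforce(g)
        assert np.nanmax(np.abs(z - zb)) < 1e-10

    def test_bruteforce_with_nodata(self, rng):
        vals = rng.random((8, 8))
        vals[2, 3] = np.nan
        vals[6, 1] = np.nan
        g = Grid.from_nan(vals, km_grid(np.zeros((8, 8))))
        z = gi_star(g).z.filled()
        zb = gi_star_bruteforce(g)
        assert np.allclose(z, zb, atol=1e-10, equal_nan=True)

    def test_high_block_is_local_max(self, rng):
        vals = rng.normal(0, 0.01, (15, 15))
        vals[6:9, 6:9] += 10.0
        z = gi_star(km_grid(vals)).z.filled()
        assert np.unravel_index(np.nanargmax(z), z.shape)[0] in (6, 7, 8)
        assert abs(z[0, 0]) < np.nanmax(z) / 2

    def test_affine_invariance(self, rng):
        vals = rng.random((12, 12))
        z1 = gi_star(km_grid(vals)).z.filled()
        z2 = gi_star(km_grid(vals * 17.0 - 4.0)).z.filled()
        assert np.allclose(z1, z2, atol=1e-9, equal_nan=True)

    def test_numerator_sums_to_zero_with_full_weights(self, rng):
        vals = rng.random((6, 6))
        n = vals.size
        # full neighborhood: every cell neighbors every other
        w = SpatialWeights(band_distance=1e9)
        g = km_grid(vals)
        kernel_sum = vals.sum()
        num = kernel_sum - vals.mean() * n  # numerator identical per cell
        assert np.isclose(num, 0.0)
        hs = gi_star(g, w)  # denominator is 0 here -> all nodata
        assert not hs.z.mask().any()

    def test_constant_field_warns_nodata(self):
        with pytest.warns(UserWarning):
            hs = gi_star(km_grid(np.full((5, 5), 3.0)))
        assert not hs.z.mask().any()

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            gi_star(km_grid(np.ones((2, 2)) * np.arange(2)))

    def test_null_calibration(self):
        rng = np.random.default_rng(7)
        fracs = []
        for _ in range(100):
            g = km_grid(rng.standard_normal((30, 30)))
            z = gi_star(g).z.filled()
            fracs.append(np.mean(np.abs(z) >= 1.96))
        assert 0.03 <= np.mean(fracs) <= 0.07


class TestClassify:
    def test_definition(self):
        z = km_grid([[2.5, -2.5, 0.3]] * 3)
        cls = classify_hotspots(HotspotGrid(z=z), alpha=0.05)
        assert cls.values[0, 0] == HOT
        assert cls.values[0, 1] == COLD
        assert cls.values[0, 2] == NS

    def test_agb_mask_demotes(self):
        z = km_grid([[2.5, 2.5]] * 3)
        value = km_grid([[150.0, 200.0]] * 3)
        cls = classify_hotspots(HotspotGrid(z=z), value=value,
                                high_mask_threshold=180.0, alpha=0.05)
        assert cls.values[0, 0] == NS and cls.values[0, 1] == HOT

    def test_nested_alpha(self, rng):
        z = km_grid(rng.normal(0, 2, (10, 10)))
        hot01 = classify_hotspots(HotspotGrid(z=z), alpha=0.01).values == HOT
        hot05 = classify_hotspots(HotspotGrid(z=z), alpha=0.05).values == HOT
        assert np.all(hot05[hot01])


class TestOverlap:
    def _cls(self, hot_cells, shape=(10, 10)):
        vals = np.full(shape, float(NS))
        for r, c in hot_cells:
            vals[r, c] = HOT
        return km_grid(vals)

    def test_identical_maps_100(self):
        a = self._cls([(0, 0), (1, 1)])
        assert overlap_percent(a, a) == 100.0

    def test_disjoint_zero(self):
        a = self._cls([(0, 0)])
        b = self._cls([(5, 5)])
        assert overlap_percent(a, b) == 0.0

    def test_hand_denominators(self):
        a_cells = [(0, c) for c in range(10)]
        b_cells = [(0, c) for c in range(5)] + [(1, c) for c in range(5)]
        a, b = self._cls(a_cells), self._cls(b_cells)
        assert np.isclose(overlap_percent(a, b, denominator="union"), 100 * 5 / 15)
        assert np.isclose(overlap_percent(a, b, denominator="first"), 50.0)
        assert np.isclose(overlap_percent(a, b, denominator="second"), 50.0)
        assert np.isclose(overlap_percent(a, b, denominator="study_area"), 5.0)

    def test_union_symmetric(self, rng):
        a = self._cls([(r, c) for r, c in rng.integers(0, 10, (8, 2))])
        b = self._cls([(r, c) for r, c in rng.integers(0, 10, (8, 2))])
        assert overlap_percent(a, b) == overlap_percent(b, a)

    def test_empty_denominator_warns_nan(self):
        a = self._cls([])
        with pytest.warns(UserWarning):
            assert np.isnan(overlap_percent(a, a))


class TestDutilleul:
    def test_iid_effective_size_near_n(self):
        ratios = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x = km_grid(rng.standard_normal((40, 40)))
            y = km_grid(rng.standard_normal((40, 40)))
            res = dutilleul_correlation(x, y)
            ratios.append(res["m_hat"] / res["n"])
        assert all(0.8 <= v <= 1.2 for v in ratios)

    def test_cosmoothed_deflation(self):
        rng = np.random.default_rng(3)
        base = ndimage.gaussian_filter(rng.standard_normal((40, 40)), 4.0)
        base /= base.std()
        x = km_grid(base + 0.05 * rng.standard_normal((40, 40)))
        y = km_grid(base + 0.05 * rng.standard_normal((40, 40)))
        res = dutilleul_correlation(x, y)
        assert res["m_hat"] < res["n"] / 2

    def test_r_equals_plain_pearson(self, rng):
        x = km_grid(rng.random((20, 20)))
        y = km_grid(rng.random((20, 20)))
        res = dutilleul_correlation(x, y)
        expect = np.corrcoef(x.values.ravel(), y.values.ravel())[0, 1]
        assert np.isclose(res["r"], expect)

    def test_effective_df_bounded(self, rng):
        x = km_grid(rng.random((15, 15)))
        y = km_grid(rng.random((15, 15)))
        res = dutilleul_correlation(x, y)
        assert res["effective_df"] <= res["n"] - 2 + 1e-9

    def test_too_few_cells_rejected(self):
        x = km_grid(np.random.default_rng(0).random((4, 4)))
        with pytest.raises(ValueError):
            dutilleul_correlation(x, x)


class TestReport:
    def test_report_structure_and_bounds(self, rng):
        base = ndimage.gaussian_filter(rng.standard_normal((25, 25)), 2.5)
        agb = km_grid((base - base.min()) / np.ptp(base) * 300)
        r1 = km_grid(np.sqrt(agb.values))
        r2 = km_grid(ndimage.gaussian_filter(rng.standard_normal((25, 25)), 2.5))
        rep = congruence_report(agb, r1, r2, alpha=0.05, agb_high_threshold=180.0)
        for val in rep.overlaps.values():
            assert np.isnan(val) or 0.0 <= val <= 100.0
        assert set(rep.correlations) == {"iucn", "endemic"}
        assert rep.classes["agb"].values.shape == (25, 25)
        d = rep.to_dict()
        assert "overlaps" in d and "correlations" in d
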