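"""Plot allometry, screening, log-log and RF models, metrics, fusion."""

import numpy as np
import pandas as pd
import pytest

from ecoscape import agb as A
from ecoscape.grids import Grid
from ecoscape.texture import TextureStack

from conftest import grid_of


class TestPlotAgb:
    def test_empty_plot_zero_with_warning(self):
        rec = A.PlotRecord("p", 0, 0, dbh_list=[])
        with pytest.warns(UserWarning):
            assert A.plot_agb(rec) == 0.0

    def test_hand_arithmetic_single_tree(self):
        coeffs = A.AllometryCoefficients(c0=np.log(1000.0), c1=0, c2=0, c3=0)
        rec = A.PlotRecord("p", 0, 0, area_ha=0.25, dbh_list=[40.0])
        assert np.isclose(A.plot_agb(rec, coeffs), 4.0)

    def test_additive_and_area_scaling(self, rng):
        dbh = rng.uniform(30, 90, 12)
        r1 = A.PlotRecord("a", 0, 0, area_ha=0.25, dbh_list=dbh)
        r2 = A.PlotRecord("b", 0, 0, area_ha=0.25, dbh_list=np.tile(dbh, 2))
        assert np.isclose(A.plot_agb(r2), 2 * A.plot_agb(r1))
        r3 = A.PlotRecord("c", 0, 0, area_ha=0.5, dbh_list=dbh)
        assert np.isclose(A.plot_agb(r3), A.plot_agb(r1) / 2)

    def test_census_threshold_enforced(self):
        with pytest.raises(ValueError):
            A.PlotRecord("p", 0, 0, dbh_list=[25.0])

    def test_allometry_inversion(self):
        for d in (30.0, 55.0, 120.0):
            m = float(A.tree_mass_kg(d))
            assert np.isclose(A.invert_tree_mass(m), d, atol=1e-6)


class TestScreening:
    def test_identical_columns_one_retained(self, rng):
        x = rng.random(10)
        t = pd.DataFrame({"a": x, "b": x, "c": rng.random(10)})
        kept = A.screen_predictors(t, 0.75)
        assert "c" in kept and len(kept) == 2

    def test_orthogonal_all_retained(self):
        t = pd.DataFrame({"a": [1, 0, 0, 1.0], "b": [0, 1, 0, 1.0],
                          "c": [0, 0, 1, -1.0]})
        if abs(t.corr()).to_numpy()[np.triu_indices(3, 1)].max() < 0.75:
            assert len(A.screen_predictors(t, 0.75)) == 3

    def test_correlated_pair_keeps_independent_column(self, rng):
        x = rng.random(30)
        t = pd.DataFrame({"a": x, "b": x + rng.normal(0, 0.01, 30),
                          "c": rng.random(30)})
        kept = A.screen_predictors(t, 0.75)
        assert "c" in kept and len(kept) == 2
        assert set(kept) - {"c"} <= {"a", "b"}

    def test_constant_column_dropped_with_warning(self, rng):
        t = pd.DataFrame({"a": np.ones(10), "b": rng.random(10),
                          "c": rng.random(10)})
        with pytest.warns(UserWarning):
            kept = A.screen_predictors(t, 0.75)
        assert "a" not in kept


class TestMetrics:
    def test_perfect_prediction(self):
        m = A.metrics([1, 2, 3.0], [1, 2, 3.0])
        assert m["r"] == 1.0 and m["rmse"] == 0.0
        assert m["mae"] == 0.0 and m["pct_bias"] == 0.0

    def test_hand_values(self):
        m = A.metrics([100.0, 100.0], [101.0, 103.0])
        assert np.isclose(m["rmse"], np.sqrt(5))
        assert np.isclose(m["mae"], 2.0)
        assert np.isclose(m["pct_bias"], 2.0)

    def test_constant_prediction_r_undefined(self):
        m = A.metrics([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
        assert np.isnan(m["r"]) and np.isfinite(m["rmse"])


class TestLogLog:
    def test_exact_power_law_recovery(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 14.0])
        y = 2.0 * x**3
        fit = A.loglog_fit(y, x)
        assert np.isclose(fit.params[0], np.log(2.0), atol=1e-10)
        assert np.isclose(fit.params[1], 3.0, atol=1e-10)
        assert np.isclose(fit.adj_r2, 1.0)
        assert np.allclose(fit.predict(x), y, rtol=1e-8)

    def test_flat_response_nonpositive_adj_r2(self, rng):
        x = rng.uniform(1, 10, 20)
        y = np.full(20, 5.0) * np.exp(rng.normal(0, 0.01, 20))
        assert A.loglog_fit(y, x).adj_r2 <= 0.05

    def test_monte_carlo_recovery_within_2se(self):
        rng = np.random.default_rng(99)
        a_true, b_true, sigma, n = np.log(3.0), 1.7, 0.2, 36
        hits = 0
        for _ in range(20):
            x = rng.uniform(5, 200, n)
            y = np.exp(a_true + b_true * np.log(x) + rng.normal(0, sigma, n))
            fit = A.loglog_fit(y, x)
            se_b = sigma / (np.sqrt(n) * np.std(np.log(x)))
            hits += abs(fit.params[1] - b_true) < 2.5 * se_b
        assert hits >= 18

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            A.loglog_fit([1.0, -2.0], [1.0, 2.0])

    def test_bias_correction_raises_mean_prediction(self, rng):
        x = rng.uniform(1, 50, 40)
        y = 2 * x * np.exp(rng.normal(0, 0.5, 40))
        on = A.loglog_fit(y, x, bias_correction=True)
        off = A.loglog_fit(y, x, bias_correction=False)
        assert np.all(on.predict(x) > off.predict(x))


class TestRf:
    def _table(self, rng, n=36, p=5):
        return pd.DataFrame(rng.random((n, p)),
                            columns=[f"v{k}" for k in range(p)])

    def test_single_predictor_dominates_importance(self, rng):
        t = self._table(rng)
        y = 10 * t["v2"].to_numpy()
        fit = A.rf_fit(t, y, folds=6, seed=0, n_estimators=100)
        assert fit.importance["v2"] == 100.0
        assert all(v < 50 for k, v in fit.importance.items() if k != "v2")

    def test_pure_noise_low_cv_r(self, rng):
        # n = 36 leaves sizeable seed-to-seed spread; the typical (median)
        # cross-validated correlation against noise must stay low
        t = self._table(rng)
        rs = []
        for seed in range(7):
            y = np.random.default_rng(seed).normal(200, 50, len(t))
            fit = A.rf_fit(t, y, folds=10, seed=seed, n_estimators=100)
            rs.append(abs(fit.cv_metrics["r"]))
        assert np.median(rs) < 0.35

    def test_fewer_plots_than_folds_warns(self, rng):
        t = self._table(rng, n=6)
        y = rng.random(6)
        with pytest.warns(UserWarning):
            A.rf_fit(t, y, folds=10, seed=0, n_estimators=20)

    def test_deterministic_given_seed(self, rng):
        t = self._table(rng)
        y = t["v0"].to_numpy() * 5 + rng.normal(0, 0.2, 36)
        f1 = A.rf_fit(t, y, folds=5, seed=3, n_estimators=50)
        f2 = A.rf_fit(t, y, folds=5, seed=3, n_estimators=50)
        assert np.array_equal(f1.cv_predictions, f2.cv_predictions)
        assert f1.importance == f2.importance


class TestPredictMap:
    def _fit_and_stack(self, rng):
        n = 36
        t = pd.DataFrame({"a": rng.random(n), "b": rng.random(n)})
        y = 100 * t["a"].to_numpy() + rng.normal(0, 5, n)
        fit = A.rf_fit(t, y, folds=5, seed=0, n_estimators=50)
        return fit, t, y

    def test_constant_stack_constant_map(self, rng):
        fit, t, y = self._fit_and_stack(rng)
        stack = TextureStack({name: grid_of(np.full((4, 4), t[name][7]))
                              for name in fit.retained_predictors})
        out = A.predict_map(fit, stack)
        assert np.allclose(out.values, out.values[0, 0])

    def test_map_bounded_by_training_range(self, rng):
        fit, t, y = self._fit_and_stack(rng)
        stack = TextureStack({name: grid_of(rng.random((6, 6)) * 3 - 1)
                              for name in fit.retained_predictors})
        out = A.predict_map(fit, stack).filled()
        assert np.nanmin(out) >= y.min() - 1e-9
        assert np.nanmax(out) <= y.max() + 1e-9

    def test_nodata_propagates(self, rng):
        fit, t, y = self._fit_and_stack(rng)
        vals = rng.random((4, 4))
        vals[1, 2] = np.nan
        grids = {}
        for name in fit.retained_predictors:
            grids[name] = Grid.from_nan(vals.copy(), grid_of(vals))
        out = A.predict_map(fit, TextureStack(grids))
        assert not out.mask()[1, 2]


class TestFusion:
    def test_identical_maps_fused_identity(self, rng):
        from scipy import ndimage
        vals = ndimage.gaussian_filter(rng.random((20, 20)), 2)
        a = grid_of(vals, cell_size=1000.0)
        b = grid_of(vals.copy(), cell_size=1000.0)
        fused, w = A.fuse_maps(a, b)
        assert np.allclose(fused.filled(), vals)
        defined = w.filled()[np.isfinite(w.filled())]
        assert np.all(defined >= 0.99)

    def test_uncorrelated_local_noise_falls_back_to_global(self, rng):
        from scipy import ndimage
        glob = ndimage.gaussian_filter(rng.standard_normal((30, 30)), 3) * 50 + 200
        local = rng.standard_normal((30, 30)) * 50 + 200
        fused, w = A.fuse_maps(grid_of(local, cell_size=1000.0),
                               grid_of(glob, cell_size=1000.0))
        diff = np.abs(fused.filled() - glob)
        assert np.nanmean(diff) < 0.35 * np.std(glob)
        assert np.nanmean(w.filled()) < 0.3

    def test_fused_within_envelope(self, rng):
        a = grid_of(rng.random((16, 16)) * 100, cell_size=1000.0)
        b = grid_of(rng.random((16, 16)) * 100, cell_size=1000.0)
        fused, _ = A.fuse_maps(a, b)
        lo = np.minimum(a.values, b.values)
        hi = np.maximum(a.values, b.values)
        f = fused.filled()
        assert np.all(f >= lo - 1e-9) and np.all(f <= hi + 1e-9)

    def test_misaligned_rejected(self):
        with pytest.raises(ValueError):
            A.fuse_maps(grid_of(np.ones((3, 3))), grid_of(np.ones((4, 4))))
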