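"""Above-ground biomass: field plots, predictor screening, models, map fusion.

Field AGB comes from 0.25-ha plots in which every stem with DBH >= 30 cm was
measured; a DBH-only ln-polynomial allometry converts each stem to kilograms:

    tree_kg = exp(c0 + c1 ln D + c2 (ln D)^2 + c3 (ln D)^3)

The default coefficients are a Brown-style moist-forest DBH-only equation
(c0 = -2.134, c1 = 2.530); they are configurable and the synthetic-scene
generator inverts the same coefficients, so plot-AGB recovery is exact by
construction.

Two model families link plot AGB to texture predictors: a log-log power law
ln(AGB) = a + b ln(x) fitted by OLS (back-transformed with the half-variance
correction exp(s^2/2)), and a random-forest regression with 10-fold
cross-validation, correlation screening at |r| >= 0.75, and out-of-bag
permutation importance.  The wall-to-wall prediction is finally fused with a
coarse global AGB map by kernel-correlation weighting: per 1-km cell, the
Pearson correlation between the two maps over kernel windows of several sizes
(negative correlations clamped to zero) becomes the convex weight given to
the local map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import ndimage, optimize
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from .grids import Grid
from .texture import TextureStack

__all__ = [
    "PlotRecord",
    "AllometryCoefficients",
    "DEFAULT_ALLOMETRY",
    "tree_mass_kg",
    "invert_tree_mass",
    "plot_agb",
    "screen_predictors",
    "metrics",
    "LogLogFit",
    "loglog_fit",
    "AgbModelFit",
    "rf_fit",
    "predict_map",
    "fuse_maps",
]


@dataclass
class AllometryCoefficients:
    """ln-polynomial DBH-only allometry, tree mass in kg for DBH in cm."""

    c0: float = -2.134
    c1: float = 2.530
    c2: float = 0.0
    c3: float = 0.0


DEFAULT_ALLOMETRY = AllometryCoefficients()


@dataclass
class PlotRecord:
    """One square field plot: center coordinate plus its tree DBH census."""

    plot_id: str
    x: float
    y: float
    area_ha: float = 0.25
    dbh_list: np.ndarray = field(default_factory=lambda: np.array([]))
    stratum: str = "primary"

    def __post_init__(self) -> None:
        self.dbh_list = np.asarray(self.dbh_list, dtype=float)
        if self.area_ha <= 0:
            raise ValueError("plot area must be positive")
        if self.dbh_list.size and np.any(self.dbh_list < 30.0 - 1e-9):
            raise ValueError("census threshold violated: DBH below 30 cm")


def tree_mass_kg(dbh_cm, coeffs: AllometryCoefficients = DEFAULT_ALLOMETRY):
    dbh_cm = np.asarray(dbh_cm, dtype=float)
    if np.any(dbh_cm <= 0):
        raise ValueError("DBH must be positive")
    ln_d = np.log(dbh_cm)
    return np.exp(coeffs.c0 + coeffs.c1 * ln_d + coeffs.c2 * ln_d**2 + coeffs.c3 * ln_d**3)


def invert_tree_mass(mass_kg: float, coeffs: AllometryCoefficients = DEFAULT_ALLOMETRY,
                     lo: float = 1.0, hi: float = 500.0) -> float:
    """DBH (cm) whose allometric mass equals ``mass_kg`` (monotone range assumed)."""
    f = lambda d: float(tree_mass_kg(d, coeffs)) - mass_kg
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError("mass outside invertible allometry range")
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


def plot_agb(record: PlotRecord,
             coeffs: AllometryCoefficients = DEFAULT_ALLOMETRY) -> float:
    """Plot biomass density in Mg per hectare."""
    if record.dbh_list.size == 0:
        warnings.warn(f"plot {record.plot_id}: empty tree list, AGB = 0")
        return 0.0
    total_kg = float(tree_mass_kg(record.dbh_list, coeffs).sum())
    return total_kg / 1000.0 / record.area_ha


def plot_predictor_table(stack: "TextureStack", plots: Sequence[PlotRecord],
                         footprint_m: float = 50.0) -> pd.DataFrame:
    """Predictor values per plot: mean of each feature over the plot footprint.

    A 0.25-ha square plot spans 50 m, i.e. a 2x2 block of 25-m cells anchored
    at the cell containing the plot center; averaging over the footprint is
    the usual plot-to-pixel matching rule.
    """
    rows = []
    for name, grid in stack.features.items():
        vals = grid.filled()
        k = max(1, int(round(footprint_m / grid.cell_size)))
        col = []
        for p in plots:
            c = int((p.x - grid.origin_x) / grid.cell_size)
            r = int((grid.origin_y - p.y) / grid.cell_size)
            block = vals[r : r + k, c : c + k]
            col.append(float(np.nanmean(block)) if np.isfinite(block).any() else np.nan)
        rows.append(pd.Series(col, name=name))
    return pd.concat(rows, axis=1)


# ---------------------------------------------------------------------------
# Predictor screening and accuracy metrics
# ---------------------------------------------------------------------------

def screen_predictors(table: pd.DataFrame, threshold: float = 0.75) -> list[str]:
    """Greedy removal of highly correlated predictors (pairwise |r| >= threshold).

    While any retained pair correlates at or above the threshold, the member
    of the worst pair with the larger mean absolute correlation to all other
    retained predictors is dropped; ties break lexicographically (the later
    name is dropped).  Constant columns carry no information and are dropped
    up front with a warning.
    """
    if table.shape[1] < 2 or table.shape[0] < 3:
        raise ValueError("need >= 2 predictors over >= 3 plots")
    cols = sorted(table.columns)
    const = [c for c in cols if table[c].nunique() <= 1]
    if const:
        warnings.warn(f"dropping constant predictor(s): {const}")
        cols = [c for c in cols if c not in const]
    while len(cols) > 1:
        corr = table[cols].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        worst = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[worst] < threshold:
            break
        i, j = sorted(worst)
        mean_i = corr[i].sum() / (len(cols) - 1)
        mean_j = corr[j].sum() / (len(cols) - 1)
        if np.isclose(mean_i, mean_j):
            drop = max(cols[i], cols[j])  # lexicographic tie rule
        else:
            drop = cols[i] if mean_i > mean_j else cols[j]
        cols.remove(drop)
    return cols


def metrics(observed, predicted) -> dict:
    """Accuracy of predictions: Pearson r, RMSE, MAE and %bias."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    resid = p - o
    out = {
        "rmse": float(np.sqrt(np.mean(resid**2))),
        "mae": float(np.mean(np.abs(resid))),
        "pct_bias": float(100.0 * resid.sum() / o.sum()),
    }
    if np.std(o) == 0 or np.std(p) == 0:
        out["r"] = np.nan
    else:
        out["r"] = float(np.corrcoef(o, p)[0, 1])
    return out


# ---------------------------------------------------------------------------
# Log-log power-law model
# ---------------------------------------------------------------------------

@dataclass
class LogLogFit:
    params: np.ndarray          # intercept a, then slopes b per predictor
    adj_r2: float
    s2: float                   # residual variance on the ln scale
    predictor_names: list
    bias_correction: bool = True

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.predictor_names) and X.shape[0] == len(self.predictor_names):
            X = X.T
        ln_pred = self.params[0] + np.log(X) @ self.params[1:]
        corr = np.exp(self.s2 / 2.0) if self.bias_correction else 1.0
        return np.exp(ln_pred) * corr


def loglog_fit(agb, predictors, names: Sequence[str] | None = None,
               bias_correction: bool = True) -> LogLogFit:
    """OLS fit of ln(AGB) = a + sum_k b_k ln(x_k) + e.

    Predictions back-transform with the half-variance correction
    exp(s^2 / 2) unless disabled.
    """
    y = np.asarray(agb, dtype=float)
    X = np.atleast_2d(np.asarray(predictors, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    if np.any(y <= 0) or np.any(X <= 0):
        raise ValueError("log-log model requires strictly positive AGB and predictors")
    design = sm.add_constant(np.log(X))
    fit = sm.OLS(np.log(y), design).fit()
    names = list(names) if names is not None else [f"x{k}" for k in range(X.shape[1])]
    return LogLogFit(
        params=np.asarray(fit.params),
        adj_r2=float(fit.rsquared_adj),
        s2=float(fit.mse_resid) if fit.df_resid > 0 else 0.0,
        predictor_names=names,
        bias_correction=bias_correction,
    )


# ---------------------------------------------------------------------------
# Random-forest model with cross-validation
# ---------------------------------------------------------------------------

@dataclass
class AgbModelFit:
    retained_predictors: list
    cv_metrics: dict            # pooled out-of-fold r / rmse / mae / pct_bias
    fold_metrics: list
    importance: dict            # predictor -> OOB permutation score in [0, 100]
    model: RandomForestRegressor
    max_features: object
    cv_predictions: np.ndarray
    responses: np.ndarray


def _oob_permutation_importance(model: RandomForestRegressor, X: np.ndarray,
                                y: np.ndarray, seed: int) -> np.ndarray:
    """Mean OOB MSE increase per permuted feature, averaged over trees."""
    rng = np.random.default_rng(seed)
    n, p = X.shape
    deltas = np.zeros(p)
    counts = np.zeros(p)
    for tree, est_idx in zip(model.estimators_, model.estimators_samples_):
        oob = np.setdiff1d(np.arange(n), est_idx)
        if oob.size < 2:
            continue
        Xo = X[oob]
        base = np.mean((y[oob] - tree.predict(Xo)) ** 2)
        for f in range(p):
            Xp = Xo.copy()
            Xp[:, f] = rng.permutation(Xp[:, f])
            err = np.mean((y[oob] - tree.predict(Xp)) ** 2)
            deltas[f] += err - base
            counts[f] += 1
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, deltas / np.maximum(counts, 1), 0.0)


def rf_fit(table: pd.DataFrame, agb, folds: int = 10, seed: int = 0,
           n_estimators: int = 500, screen_threshold: float = 0.75,
           mtry_grid: Sequence | None = None) -> AgbModelFit:
    """Random-forest AGB model with correlation screening and k-fold CV.

    The trees-per-split parameter (``max_features``) is tuned over a small
    grid by pooled cross-validated correlation; the pooled out-of-fold
    predictions give the reported r / RMSE / MAE / %bias, and permutation
    importance on out-of-bag samples (rescaled so the best predictor scores
    100) ranks the predictors.
    """
    y = np.asarray(agb, dtype=float)
    retained = screen_predictors(table, threshold=screen_threshold)
    X = table[retained].to_numpy(dtype=float)
    n, p = X.shape
    if n < folds:
        warnings.warn(f"only {n} plots: reducing folds from {folds} to {n}")
        folds = n
    if mtry_grid is None:
        mtry_grid = sorted({max(1, p // 3), max(1, int(np.sqrt(p))), max(1, p // 2)})

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))

    def pooled_cv(mtry):
        preds = np.empty(n)
        for tr, te in splits:
            rf = RandomForestRegressor(
                n_estimators=n_estimators, max_features=mtry, random_state=seed,
                bootstrap=True, n_jobs=1)
            rf.fit(X[tr], y[tr])
            preds[te] = rf.predict(X[te])
        return preds

    best = None
    for mtry in mtry_grid:
        preds = pooled_cv(mtry)
        r = metrics(y, preds)["r"]
        score = -np.inf if np.isnan(r) else r
        if best is None or score > best[0]:
            best = (score, mtry, preds)
    _, best_mtry, cv_preds = best

    fold_metrics = [metrics(y[te], cv_preds[te]) for _, te in splits]
    pooled = metrics(y, cv_preds)

    final = RandomForestRegressor(
        n_estimators=n_estimators, max_features=best_mtry, random_state=seed,
        bootstrap=True, oob_score=True, n_jobs=1)
    final.fit(X, y)
    raw_imp = np.maximum(_oob_permutation_importance(final, X, y, seed), 0.0)
    if raw_imp.max() > 0:
        scores = 100.0 * raw_imp / raw_imp.max()
    else:
        scores = np.zeros(p)
    importance = {name: float(s) for name, s in zip(retained, scores)}

    return AgbModelFit(
        retained_predictors=retained,
        cv_metrics=pooled,
        fold_metrics=fold_metrics,
        importance=importance,
        model=final,
        max_features=best_mtry,
        cv_predictions=cv_preds,
        responses=y,
    )


def predict_map(fit: AgbModelFit, stack: TextureStack,
                batch: int = 200_000) -> Grid:
    """Wall-to-wall prediction over the retained predictor grids.

    Any cell with a nodata predictor is nodata in the output.
    """
    grids = [stack[name] for name in fit.retained_predictors]
    template = grids[0]
    for g in grids[1:]:
        template.require_aligned(g, "predictor grids")
    planes = [g.filled().ravel() for g in grids]
    Xall = np.column_stack(planes)
    valid = np.all(np.isfinite(Xall), axis=1)
    out = np.full(Xall.shape[0], np.nan)
    idx = np.flatnonzero(valid)
    for start in range(0, idx.size, batch):
        sel = idx[start : start + batch]
        out[sel] = fit.model.predict(Xall[sel])
    return Grid.from_nan(out.reshape(template.shape), template)


# ---------------------------------------------------------------------------
# Local/global map fusion
# ---------------------------------------------------------------------------

def _windowed_pearson(a: np.ndarray, b: np.ndarray, size: int) -> np.ndarray:
    """Per-cell Pearson r of two fields over a centered size x size window,
    nodata (NaN) aware.  Zero-variance windows give NaN."""
    ok = np.isfinite(a) & np.isfinite(b)
    a0 = np.where(ok, a, 0.0)
    b0 = np.where(ok, b, 0.0)
    kernel = np.ones((size, size))

    def _s(arr):
        return ndimage.convolve(arr, kernel, mode="constant", cval=0.0)

    n = _s(ok.astype(float))
    sa, sb = _s(a0), _s(b0)
    saa, sbb, sab = _s(a0**2), _s(b0**2), _s(a0 * b0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sab - sa * sb
        var_a = n * saa - sa**2
        var_b = n * sbb - sb**2
        r = cov / np.sqrt(var_a * var_b)
    r[(n < 2) | (var_a <= 0) | (var_b <= 0)] = np.nan
    return r


def fuse_maps(local: Grid, global_map: Grid,
              kernel_sizes: Sequence[int] = (4, 8, 16)) -> tuple[Grid, Grid]:
    """Kernel-correlation fusion of a local AGB map with a global one.

    Both maps must already live on the same (1-km) grid.  For every cell the
    Pearson correlation between the maps over each kernel window is computed;
    negative correlations are clamped to zero (an anti-correlated local map
    earns no trust) and a zero-variance window contributes zero weight.  The
    clamped correlations are averaged across kernel sizes into the weight
    ``w`` of the convex combination ``fused = w * local + (1 - w) * global``.

    Returns ``(fused, weight)``.
    """
    local.require_aligned(global_map, "local/global AGB maps")
    a = local.filled()
    b = global_map.filled()
    weights = []
    for size in kernel_sizes:
        r = _windowed_pearson(a, b, int(size))
        w = np.clip(r, 0.0, 1.0)
        w[~np.isfinite(r)] = 0.0
        weights.append(w)
    w = np.mean(weights, axis=0)
    fused = w * a + (1.0 - w) * b
    bad = ~np.isfinite(a) | ~np.isfinite(b)
    fused[bad] = np.nan
    wout = w.copy()
    wout[bad] = np.nan
    return Grid.from_nan(fused, local), Grid.from_nan(wout, local)
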