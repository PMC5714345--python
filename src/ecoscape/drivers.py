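"""Richness-driver analysis: predictor stack, SVR model, importance, curves.

The 1-km predictor stack mirrors the study's variable list: AGB, aspect,
road distance, altitude, slope, RFDI, landscape diversity, fragmentation,
annual rainfall, river distance, mean temperature and precipitation
seasonality.  A radial-kernel support-vector regression models richness over
a random sample of complete cells (1500 by default), and each predictor's
importance is the R-squared of a univariate local-regression smoother of
richness on that predictor against the intercept-only null, rescaled so the
best predictor scores 100.  Partial-dependence curves are computed by
clamping one predictor across its observed range and averaging model
predictions over all sampled cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .grids import Grid, aggregate, aggregate_circular

__all__ = [
    "DriverSample",
    "ImportanceTable",
    "build_stack",
    "sample_cells",
    "SvrFit",
    "svr_fit",
    "rank_importance",
    "rf_surrogate",
    "partial_dependence",
    "direction_of_effect",
]


@dataclass
class DriverSample:
    """Sampled 1-km cells with predictor matrix X and richness response y."""

    cells: np.ndarray            # flat row-major indices into the template
    X: pd.DataFrame
    y: np.ndarray
    template: Grid


@dataclass
class ImportanceTable:
    scores: dict                 # predictor -> importance on [0, 100]
    raw_r2: dict                 # predictor -> smoother R^2 vs null

    def ranked(self) -> list:
        return sorted(self.scores, key=lambda k: (-self.scores[k], k))


def build_stack(layers: dict, template: Grid,
                circular: tuple = ("aspect",),
                categorical: tuple = ()) -> dict:
    """Aggregate/align named base-resolution grids onto the 1-km template.

    Continuous layers aggregate by block mean, angular layers (aspect) by the
    circular mean, categorical layers by majority.  Layers already on the
    template pass through unchanged.
    """
    out = {}
    for name, grid in layers.items():
        if grid.aligned_with(template):
            out[name] = grid.like(grid.values.copy())
            continue
        factor = template.cell_size / grid.cell_size
        if abs(factor - round(factor)) > 1e-9 or factor < 1:
            raise ValueError(f"layer {name!r}: cell size incompatible with template")
        factor = int(round(factor))
        if (grid.n_rows + factor - 1) // factor < template.n_rows or \
           (grid.n_cols + factor - 1) // factor < template.n_cols:
            raise ValueError(f"layer {name!r}: extent does not cover the template")
        if name in circular:
            agg = aggregate_circular(grid, factor)
        elif name in categorical:
            agg = aggregate(grid, factor, "majority")
        else:
            agg = aggregate(grid, factor, "mean")
        agg.values = agg.values[: template.n_rows, : template.n_cols]
        agg.origin_x, agg.origin_y = template.origin_x, template.origin_y
        out[name] = agg
    return out


def sample_cells(stack: dict, richness: Grid, n: int = 1500,
                 seed: int = 0) -> DriverSample:
    """Uniform sample without replacement over complete (no-nodata) cells."""
    names = sorted(stack)
    planes = []
    for name in names:
        richness.require_aligned(stack[name], f"stack layer {name!r}")
        planes.append(stack[name].filled().ravel())
    y = richness.filled().ravel()
    complete = np.all(np.isfinite(np.column_stack(planes + [y])), axis=1)
    idx = np.flatnonzero(complete)
    if idx.size == 0:
        raise ValueError("no complete cells to sample")
    if idx.size < n:
        warnings.warn(f"only {idx.size} complete cells available (requested {n})")
        chosen = idx
    else:
        rng = np.random.default_rng(seed)
        chosen = np.sort(rng.choice(idx, size=n, replace=False))
    X = pd.DataFrame({name: plane[chosen] for name, plane in zip(names, planes)})
    return DriverSample(cells=chosen, X=X, y=y[chosen], template=richness)


@dataclass
class SvrFit:
    model: Pipeline
    cv_r2: float
    params: dict
    predictor_names: list

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.model.predict(np.asarray(X[self.predictor_names], dtype=float))


def svr_fit(sample: DriverSample, folds: int = 10, seed: int = 0,
            c_grid=(1.0, 10.0, 100.0), gamma_grid=("scale", 0.1, 0.5)) -> SvrFit:
    """Radial-kernel epsilon-SVR with internal standardization and CV tuning."""
    y = sample.y
    if np.std(y) == 0:
        raise ValueError("degenerate response: richness is constant")
    X = np.asarray(sample.X, dtype=float)
    pipe = Pipeline([("scale", StandardScaler()), ("svr", SVR(kernel="rbf"))])
    grid = {"svr__C": list(c_grid), "svr__gamma": list(gamma_grid)}
    cv = KFold(n_splits=min(folds, len(y)), shuffle=True, random_state=seed)
    search = GridSearchCV(pipe, grid, cv=cv, scoring="r2", n_jobs=1)
    search.fit(X, y)
    return SvrFit(model=search.best_estimator_,
                  cv_r2=float(search.best_score_),
                  params=dict(search.best_params_),
                  predictor_names=list(sample.X.columns))


def rank_importance(sample: DriverSample, span: float = 0.75) -> ImportanceTable:
    """Smoother-R^2 variable importance on [0, 100].

    For each predictor independently a locally weighted regression of the
    response on that predictor (span 0.75) is fitted; the importance is
    max(0, 1 - SSE_smoother / SSE_null) against the intercept-only model,
    rescaled so the top predictor scores 100.
    """
    if len(sample.y) < 30:
        raise ValueError("need at least 30 sampled cells")
    y = sample.y
    sse_null = float(np.sum((y - y.mean()) ** 2))
    raw = {}
    for name in sample.X.columns:
        x = sample.X[name].to_numpy(dtype=float)
        if np.ptp(x) == 0 or sse_null == 0:
            raw[name] = 0.0
            continue
        smoothed = sm.nonparametric.lowess(
            y, x, frac=span, delta=0.01 * np.ptp(x), return_sorted=True)
        yhat = np.interp(x, smoothed[:, 0], smoothed[:, 1])
        sse = float(np.sum((y - yhat) ** 2))
        raw[name] = max(0.0, 1.0 - sse / sse_null)
    top = max(raw.values())
    if top > 0:
        scores = {k: 100.0 * v / top for k, v in raw.items()}
    else:
        scores = {k: 0.0 for k in raw}
    return ImportanceTable(scores=scores, raw_r2=raw)


def rf_surrogate(sample: DriverSample, seed: int = 0,
                 n_estimators: int = 300) -> RandomForestRegressor:
    """Random-forest surrogate refit to the sample, for partial dependence."""
    rf = RandomForestRegressor(n_estimators=n_estimators, random_state=seed, n_jobs=1)
    rf.fit(np.asarray(sample.X, dtype=float), sample.y)
    return rf


def partial_dependence(model, sample: DriverSample, predictor: str,
                       n_points: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """Clamp-and-average partial dependence curve over the observed range."""
    if predictor not in sample.X.columns:
        raise ValueError(f"predictor {predictor!r} not in the sample")
    x = sample.X[predictor].to_numpy(dtype=float)
    grid = np.linspace(x.min(), x.max(), n_points)
    X = np.asarray(sample.X, dtype=float)
    col = list(sample.X.columns).index(predictor)
    n = X.shape[0]
    # one batched prediction: n_points stacked copies, each clamped
    Xc = np.repeat(X[None, :, :], n_points, axis=0)
    Xc[:, :, col] = grid[:, None]
    preds = model.predict(Xc.reshape(n_points * n, -1))
    curve = preds.reshape(n_points, n).mean(axis=1)
    return grid, curve


def direction_of_effect(sample: DriverSample, predictor: str) -> dict:
    """Signed Pearson correlation of the response with one predictor.

    Classical (spatially uncorrected) two-sided p; the autocorrelation-aware
    test lives in the congruence module.
    """
    x = sample.X[predictor].to_numpy(dtype=float)
    r, p = stats.pearsonr(x, sample.y)
    label = "p<0.01" if p < 0.01 else ("p<0.05" if p < 0.05 else "ns")
    return {"r": float(r), "p": float(p), "label": label}
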