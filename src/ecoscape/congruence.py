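"""Hot/coldspot congruence between biomass and richness.

Three statistics carry the headline analysis:

* **Getis-Ord Gi*** — for every cell, a z-score measuring whether the values
  within its neighborhood (a fixed distance band including the cell itself)
  are unusually high (hotspot) or low (coldspot) relative to the whole field:

      z_i = (sum_j w_ij x_j - Xbar W_i) /
            (S * sqrt((n C_i - W_i^2) / (n - 1)))

  with binary weights w_ij, W_i = sum_j w_ij, C_i = sum_j w_ij^2, and Xbar, S
  the global mean and population SD over the n data cells.

* **Percent area overlap** of hot (or cold) classes between two layers, under
  four denominator conventions (union of the two class sets, either single
  set, or the whole study area) since the convention behind published overlap
  figures is rarely stated.

* **Modified (Dutilleul-style) correlation** — plain Pearson r whose
  significance test replaces the sample size with an effective size M
  estimated from the two fields' spatial autocovariance over distance
  classes: Var(r) = tr(B Sx B Sy) / (tr(B Sx) tr(B Sy)) with B the centering
  matrix and Sx, Sy the distance-class autocovariance matrices, and
  M = 1 + 1/Var(r).  For independent fields M ~ n; co-smoothed fields
  deflate M and hence the degrees of freedom M - 2 of the t reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .grids import Grid

__all__ = [
    "HOT", "COLD", "NS", "NODATA_CLASS",
    "SpatialWeights",
    "HotspotGrid",
    "gi_star",
    "classify_hotspots",
    "overlap_percent",
    "dutilleul_correlation",
    "CongruenceReport",
    "congruence_report",
]

HOT, NS, COLD, NODATA_CLASS = 1, 0, -1, -9


@dataclass
class SpatialWeights:
    """Binary neighborhood weights for the local statistic."""

    scheme: str = "fixed_distance_band"
    band_distance: float = 3000.0
    include_self: bool = True

    def kernel(self, cell_size: float, max_reach: int | None = None) -> np.ndarray:
        if self.scheme == "queen":
            k = np.ones((3, 3), dtype=bool)
        elif self.scheme == "fixed_distance_band":
            reach = int(np.floor(self.band_distance / cell_size))
            if max_reach is not None:
                reach = min(reach, max_reach)
            dr = np.arange(-reach, reach + 1)
            dd = np.hypot(dr[:, None], dr[None, :]) * cell_size
            k = dd <= self.band_distance + 1e-9
        else:
            raise ValueError(f"unknown weights scheme {self.scheme!r}")
        center = tuple(s // 2 for s in k.shape)
        k[center] = self.include_self
        return k


@dataclass
class HotspotGrid:
    z: Grid
    alpha: float = 0.05
    classes: Grid | None = None


def gi_star(x: Grid, weights: SpatialWeights | None = None) -> HotspotGrid:
    """Getis-Ord Gi* z-score for every data cell.

    Vectorized over the grid by convolving the value field and the data mask
    with the binary neighborhood kernel.  A constant field has no spatial
    structure to standardize and yields all-nodata with a warning.
    """
    weights = weights or SpatialWeights()
    vals = x.filled()
    valid = np.isfinite(vals)
    n = int(valid.sum())
    if n < 9:
        raise ValueError("Gi* needs at least 9 data cells")
    xbar = vals[valid].mean()
    s = vals[valid].std(ddof=0)
    if s == 0:
        warnings.warn("Gi*: constant field, all z-scores undefined")
        return HotspotGrid(z=Grid.from_nan(np.full(vals.shape, np.nan), x))

    kernel = weights.kernel(x.cell_size,
                            max_reach=max(x.shape)).astype(float)
    v0 = np.where(valid, vals, 0.0)
    conv = lambda a: ndimage.convolve(a, kernel, mode="constant", cval=0.0)
    wx = conv(v0)
    wi = conv(valid.astype(float))      # W_i; binary weights make C_i = W_i
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = s * np.sqrt((n * wi - wi**2) / (n - 1))
        z = (wx - xbar * wi) / denom
    z[~valid] = np.nan
    z[(wi == 0) | ~np.isfinite(z)] = np.nan
    return HotspotGrid(z=Grid.from_nan(z, x))


def classify_hotspots(hs: HotspotGrid, value: Grid | None = None,
                      high_mask_threshold: float | None = None,
                      alpha: float | None = None) -> Grid:
    """Classes {HOT, COLD, NS, NODATA} from z-scores at significance alpha.

    When a high-value mask threshold is given (180 Mg/ha for AGB layers),
    hotspot cells must additionally exceed it in the value grid.
    """
    alpha = hs.alpha if alpha is None else alpha
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    z = hs.z.filled()
    cls = np.full(z.shape, float(NS))
    cls[z >= z_crit] = HOT
    cls[z <= -z_crit] = COLD
    if high_mask_threshold is not None:
        if value is None:
            raise ValueError("high_mask_threshold requires the value grid")
        hs.z.require_aligned(value, "z/value grids")
        vals = value.filled()
        demote = (cls == HOT) & ~(vals > high_mask_threshold)
        cls[demote] = NS
    cls[~np.isfinite(z)] = NODATA_CLASS
    out = hs.z.like(cls, nodata=float(NODATA_CLASS))
    hs.classes = out
    hs.alpha = alpha
    return out


def overlap_percent(a: Grid, b: Grid, which: int = HOT,
                    denominator: str = "union") -> float:
    """Percent of cells sharing a hotspot class between two class grids.

    ``denominator``: 'union' (default), 'first', 'second' or 'study_area'
    (all cells with data in both grids).
    """
    a.require_aligned(b, "class grids")
    ca, cb = a.values, b.values
    in_a = ca == which
    in_b = cb == which
    both = np.count_nonzero(in_a & in_b)
    if denominator == "union":
        denom = np.count_nonzero(in_a | in_b)
    elif denominator == "first":
        denom = np.count_nonzero(in_a)
    elif denominator == "second":
        denom = np.count_nonzero(in_b)
    elif denominator == "study_area":
        denom = np.count_nonzero((ca != NODATA_CLASS) & (cb != NODATA_CLASS))
    else:
        raise ValueError(f"unknown denominator convention {denominator!r}")
    if denom == 0:
        warnings.warn("overlap_percent: empty denominator")
        return float("nan")
    return 100.0 * both / denom


def _distance_classes(n_pairs: int, cap: int = 30) -> int:
    return int(min(cap, np.ceil(np.log2(max(n_pairs, 2))) + 1))


def dutilleul_correlation(x: Grid, y: Grid,
                          n_distance_classes: int | None = None,
                          max_cells: int = 2500, seed: int = 0) -> dict:
    """Pearson correlation with autocorrelation-corrected degrees of freedom.

    The reported r is the ordinary Pearson correlation of the paired cells —
    the correction only changes the effective sample size M and hence the t
    test.  Distance classes default to a Sturges count on the pairwise
    distances (capped at 30, equal width).  Very large grids are thinned to
    ``max_cells`` cells (seeded) to bound the n x n covariance algebra.
    """
    x.require_aligned(y, "correlation grids")
    xv = x.filled().ravel()
    yv = y.filled().ravel()
    ok = np.isfinite(xv) & np.isfinite(yv)
    idx = np.flatnonzero(ok)
    if idx.size < 20:
        raise ValueError("need at least 20 paired data cells")
    if idx.size > max_cells:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(idx, size=max_cells, replace=False))
    xs = xv[idx]
    ys = yv[idx]
    n = idx.size

    r = float(np.corrcoef(xs, ys)[0, 1])

    xx, yy = x.cell_centers()
    px = xx.ravel()[idx]
    py = yy.ravel()[idx]
    d = np.hypot(px[:, None] - px[None, :], py[:, None] - py[None, :])

    n_pairs = n * (n - 1) // 2
    k = n_distance_classes or _distance_classes(n_pairs)
    if k < 3:
        raise ValueError("fewer than 3 distance classes supportable")
    dmax = d.max()
    edges = np.linspace(0.0, dmax, k + 1)
    cls = np.clip(np.digitize(d, edges[1:-1]), 0, k - 1)
    cls[d == 0] = -1  # self pairs handled by the diagonal

    def autocov_matrix(v: np.ndarray) -> np.ndarray:
        c = v - v.mean()
        prod = np.outer(c, c)
        cov = np.zeros((n, n))
        for kk in range(k):
            sel = cls == kk
            if sel.any():
                cov[sel] = prod[sel].mean()
        np.fill_diagonal(cov, c @ c / n)
        return cov

    sx = autocov_matrix(xs)
    sy = autocov_matrix(ys)

    def center(m: np.ndarray) -> np.ndarray:
        m = m - m.mean(axis=0, keepdims=True)
        return m - m.mean(axis=1, keepdims=True)

    bsx = center(sx)
    bsy = center(sy)
    num = float(np.sum(bsx * bsy.T))             # tr(B Sx B Sy)
    den = float(np.trace(bsx) * np.trace(bsy))
    var_r = num / den if den > 0 else 1.0 / (n - 1)
    var_r = max(var_r, 1.0 / (n - 1))            # cannot beat independence
    m_hat = 1.0 + 1.0 / var_r
    eff_df = m_hat - 2.0
    if abs(r) < 1.0 and eff_df > 0:
        t = r * np.sqrt(eff_df / (1.0 - r**2))
        p = float(2.0 * stats.t.sf(abs(t), eff_df))
    else:
        t, p = np.inf if r != 0 else 0.0, 0.0 if r != 0 else 1.0
    return {"r": r, "m_hat": float(m_hat), "effective_df": float(eff_df),
            "t": float(t), "p": p, "n": n, "n_distance_classes": int(k)}


@dataclass
class CongruenceReport:
    """Hotspot classes and congruence statistics for AGB vs richness strata."""

    alpha: float
    agb_high_threshold: float
    classes: dict = field(default_factory=dict)      # layer -> class Grid
    z: dict = field(default_factory=dict)            # layer -> z Grid
    overlaps: dict = field(default_factory=dict)     # (stratum, which, denom) -> %
    correlations: dict = field(default_factory=dict)  # stratum -> dutilleul dict

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "agb_high_threshold": self.agb_high_threshold,
            "overlaps": {f"{s}|{w}|{d}": v
                         for (s, w, d), v in self.overlaps.items()},
            "correlations": self.correlations,
        }


def congruence_report(agb_1km: Grid, richness_iucn: Grid,
                      richness_endemic: Grid,
                      weights: SpatialWeights | None = None,
                      alpha: float = 0.05,
                      agb_high_threshold: float = 180.0) -> CongruenceReport:
    """Full congruence computation between AGB and the two richness strata.

    Runs Gi* + classification on all three layers (the AGB hotspot class
    additionally requires AGB above the high-value threshold), then computes
    hot-hot and cold-cold percent overlaps under all four denominator
    conventions and the corrected correlations for both AGB-richness pairs.
    """
    weights = weights or SpatialWeights()
    report = CongruenceReport(alpha=alpha, agb_high_threshold=agb_high_threshold)

    layers = {"agb": (agb_1km, agb_high_threshold),
              "iucn": (richness_iucn, None),
              "endemic": (richness_endemic, None)}
    for name, (grid, thr) in layers.items():
        hs = gi_star(grid, weights)
        hs.alpha = alpha
        cls = classify_hotspots(hs, value=grid, high_mask_threshold=thr)
        report.z[name] = hs.z
        report.classes[name] = cls

    which_names = {HOT: "hot", COLD: "cold"}
    for stratum in ("iucn", "endemic"):
        for which in (HOT, COLD):
            for denom in ("union", "first", "second", "study_area"):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    val = overlap_percent(report.classes["agb"],
                                          report.classes[stratum],
                                          which=which, denominator=denom)
                report.overlaps[(stratum, which_names[which], denom)] = val
        richness = layers[stratum][0]
        report.correlations[stratum] = dutilleul_correlation(agb_1km, richness)
    return report
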