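"""Moving-window grey-level co-occurrence (GLCM) texture features.

Texture is the predictor engine of the biomass model: backscatter itself
saturates above roughly 100 Mg/ha, but the fine-scale arrangement of bright
and dark pixels keeps changing with canopy structure, and the GLCM captures
exactly that — the joint frequency of quantized pixel-value pairs at small
spatial offsets.

Eight Haralick statistics are computed from the window GLCM (levels default
32, window 5x5, distance-1 offsets in the four directions, symmetric):

    mean            mu    = sum_ij i * P(i, j)
    variance        sum_ij (i - mu)^2 * P
    homogeneity     sum_ij P / (1 + (i - j)^2)
    contrast        sum_ij (i - j)^2 * P
    dissimilarity   sum_ij |i - j| * P
    entropy         -sum_ij P * ln(P)
    second_moment   sum_ij P^2          (ASM / energy)
    correlation     sum_ij (i - mu_i)(j - mu_j) P / (sigma_i * sigma_j)

First-order windowed statistics of the raw (unquantized) values are produced
alongside, since both first- and second-order texture enter the AGB model.

Two execution engines exist: a numba kernel for wall-to-wall maps and a plain
per-cell python path; they are required to agree exactly and the python path
doubles as the test oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import ndimage

from .grids import Grid

__all__ = [
    "TextureConfig",
    "TextureStack",
    "FEATURE_NAMES",
    "quantize",
    "glcm",
    "haralick_features",
    "texture_stack",
]

FEATURE_NAMES = (
    "mean",
    "variance",
    "homogeneity",
    "contrast",
    "dissimilarity",
    "entropy",
    "second_moment",
    "correlation",
)

DEFAULT_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


@dataclass
class TextureConfig:
    levels: int = 32
    window: int = 5
    offsets: tuple = DEFAULT_OFFSETS
    symmetric: bool = True
    features: tuple = FEATURE_NAMES
    first_order: bool = True

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be an odd integer >= 3")
        for dr, dc in self.offsets:
            if dr == 0 and dc == 0:
                raise ValueError("offsets must be non-zero")
        unknown = set(self.features) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown texture features: {sorted(unknown)}")


@dataclass
class TextureStack:
    """Named, mutually aligned texture feature grids."""

    features: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> Grid:
        return self.features[name]

    def names(self) -> list:
        return list(self.features)

    def update(self, other: "TextureStack") -> None:
        self.features.update(other.features)


def quantize(grid: Grid, levels: int = 32) -> Grid:
    """Linear min-max binning of a grid into integer levels {0..levels-1}.

    The maximum maps to levels-1; nodata is preserved.  A constant grid is
    degenerate (no contrast to quantize) and maps to all zeros with a warning.
    """
    vals = grid.filled()
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        raise ValueError("cannot quantize an all-nodata grid")
    lo, hi = finite.min(), finite.max()
    if lo == hi:
        warnings.warn("quantize: constant grid, emitting all zeros")
        q = np.zeros_like(vals)
    else:
        q = np.floor((vals - lo) / (hi - lo) * levels)
        q = np.clip(q, 0, levels - 1)
    q[~np.isfinite(vals)] = np.nan
    return Grid.from_nan(q, grid)


def glcm(window_values: np.ndarray, config: TextureConfig) -> np.ndarray:
    """Co-occurrence probability matrix of one window of quantized values.

    Pair counts at each configured offset are accumulated (both orientations
    when symmetric) and normalized to sum 1.  NaN cells never pair.
    """
    w = np.asarray(window_values, dtype=float)
    L = config.levels
    counts = np.zeros((L, L))
    nr, nc = w.shape
    for dr, dc in config.offsets:
        r0, r1 = max(0, -dr), min(nr, nr - dr)
        c0, c1 = max(0, -dc), min(nc, nc - dc)
        a = w[r0:r1, c0:c1]
        b = w[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        ok = np.isfinite(a) & np.isfinite(b)
        ai = a[ok].astype(int)
        bi = b[ok].astype(int)
        np.add.at(counts, (ai, bi), 1.0)
        if config.symmetric:
            np.add.at(counts, (bi, ai), 1.0)
    total = counts.sum()
    if total == 0:
        raise ValueError("window too small for the configured offsets: no pairs")
    return counts / total


def haralick_features(P: np.ndarray) -> dict:
    """All eight Haralick statistics of a normalized GLCM."""
    if not np.isclose(P.sum(), 1.0, atol=1e-8):
        raise ValueError("GLCM must be normalized to sum 1")
    L = P.shape[0]
    i = np.arange(L)[:, None] * np.ones((1, L))
    j = np.arange(L)[None, :] * np.ones((L, 1))
    mu = float((i * P).sum())
    variance = float(((i - mu) ** 2 * P).sum())
    diff = i - j
    homogeneity = float((P / (1.0 + diff**2)).sum())
    contrast = float((diff**2 * P).sum())
    dissimilarity = float((np.abs(diff) * P).sum())
    pos = P[P > 0]
    entropy = float(-(pos * np.log(pos)).sum())
    asm = float((P**2).sum())
    mu_i = float((i * P).sum())
    mu_j = float((j * P).sum())
    var_i = float(((i - mu_i) ** 2 * P).sum())
    var_j = float(((j - mu_j) ** 2 * P).sum())
    sd = np.sqrt(var_i * var_j)
    correlation = float((((i - mu_i) * (j - mu_j) * P).sum()) / sd) if sd > 0 else np.nan
    return {
        "mean": mu,
        "variance": variance,
        "homogeneity": homogeneity,
        "contrast": contrast,
        "dissimilarity": dissimilarity,
        "entropy": entropy,
        "second_moment": asm,
        "correlation": correlation,
    }


@njit(cache=True)
def _stack_kernel(q, valid, levels, half, offsets, symmetric):  # pragma: no cover
    nr, nc = q.shape
    nfeat = 8
    out = np.full((nfeat, nr, nc), np.nan)
    P = np.zeros((levels, levels))
    win = 2 * half + 1
    max_touched = 2 * offsets.shape[0] * win * win
    touched = np.empty((max_touched, 2), dtype=np.int32)
    for r in range(half, nr - half):
        for c in range(half, nc - half):
            n_touched = 0
            total = 0.0
            for k in range(offsets.shape[0]):
                dr = offsets[k, 0]
                dc = offsets[k, 1]
                for wr in range(r - half, r + half + 1):
                    for wc in range(c - half, c + half + 1):
                        r2 = wr + dr
                        c2 = wc + dc
                        if r2 < r - half or r2 > r + half:
                            continue
                        if c2 < c - half or c2 > c + half:
                            continue
                        if not valid[wr, wc] or not valid[r2, c2]:
                            continue
                        a = q[wr, wc]
                        b = q[r2, c2]
                        if P[a, b] == 0.0:
                            touched[n_touched, 0] = a
                            touched[n_touched, 1] = b
                            n_touched += 1
                        P[a, b] += 1.0
                        total += 1.0
                        if symmetric:
                            if P[b, a] == 0.0:
                                touched[n_touched, 0] = b
                                touched[n_touched, 1] = a
                                n_touched += 1
                            P[b, a] += 1.0
                            total += 1.0
            if total == 0.0:
                continue
            mu = 0.0
            homog = 0.0
            contrast = 0.0
            dissim = 0.0
            entropy = 0.0
            asm = 0.0
            mu_j = 0.0
            for t in range(n_touched):
                a = touched[t, 0]
                b = touched[t, 1]
                p = P[a, b] / total
                d = a - b
                mu += a * p
                mu_j += b * p
                homog += p / (1.0 + d * d)
                contrast += d * d * p
                dissim += abs(d) * p
                entropy -= p * np.log(p)
                asm += p * p
            var_i = 0.0
            var_j = 0.0
            cov = 0.0
            for t in range(n_touched):
                a = touched[t, 0]
                b = touched[t, 1]
                p = P[a, b] / total
                var_i += (a - mu) * (a - mu) * p
                var_j += (b - mu_j) * (b - mu_j) * p
                cov += (a - mu) * (b - mu_j) * p
            for t in range(n_touched):
                P[touched[t, 0], touched[t, 1]] = 0.0
            out[0, r, c] = mu
            out[1, r, c] = var_i
            out[2, r, c] = homog
            out[3, r, c] = contrast
            out[4, r, c] = dissim
            out[5, r, c] = entropy
            out[6, r, c] = asm
            if var_i > 0.0 and var_j > 0.0:
                out[7, r, c] = cov / np.sqrt(var_i * var_j)
    return out


def _stack_python(q, valid, config: TextureConfig) -> np.ndarray:
    """Per-cell brute force: glcm() + haralick_features() at every cell."""
    nr, nc = q.shape
    half = config.window // 2
    out = np.full((len(FEATURE_NAMES), nr, nc), np.nan)
    qf = np.where(valid, q.astype(float), np.nan)
    for r in range(half, nr - half):
        for c in range(half, nc - half):
            win = qf[r - half : r + half + 1, c - half : c + half + 1]
            if not np.isfinite(win).any():
                continue
            try:
                P = glcm(win, config)
            except ValueError:
                continue
            feats = haralick_features(P)
            for fi, name in enumerate(FEATURE_NAMES):
                out[fi, r, c] = feats[name]
    return out


def texture_stack(
    grid: Grid,
    config: TextureConfig | None = None,
    band_name: str = "band",
    engine: str = "numba",
) -> TextureStack:
    """Per-cell Haralick features over a centered moving window.

    Border cells (incomplete window) are nodata.  Output grids are aligned
    with the input and named ``{band_name}_{feature}``; first-order windowed
    mean/variance of the raw values are added as ``{band_name}_fo_mean`` and
    ``{band_name}_fo_variance`` when configured.
    """
    config = config or TextureConfig()
    if config.window > min(grid.shape):
        raise ValueError("texture window larger than the grid")
    qgrid = quantize(grid, config.levels)
    valid = qgrid.mask()
    q = np.where(valid, qgrid.values, 0).astype(np.int32)
    half = config.window // 2
    offsets = np.asarray(config.offsets, dtype=np.int64)
    if engine == "numba":
        cube = _stack_kernel(q, valid, config.levels, half, offsets, config.symmetric)
    elif engine == "python":
        cube = _stack_python(q, valid, config)
    else:
        raise ValueError(f"unknown engine {engine!r}")

    stack = TextureStack()
    for fi, name in enumerate(FEATURE_NAMES):
        if name in config.features:
            stack.features[f"{band_name}_{name}"] = Grid.from_nan(cube[fi], grid)

    if config.first_order:
        vals = grid.filled()
        v0 = np.where(np.isfinite(vals), vals, 0.0)
        ok = np.isfinite(vals).astype(float)
        kernel = np.ones((config.window, config.window))

        def _wsum(a):
            return ndimage.convolve(a, kernel, mode="constant", cval=0.0)

        n = _wsum(ok)
        with np.errstate(divide="ignore", invalid="ignore"):
            mean = _wsum(v0) / n
            var = np.maximum(_wsum(v0**2) / n - mean**2, 0.0)
        interior = np.zeros(vals.shape, dtype=bool)
        interior[half:-half or None, half:-half or None] = True
        bad = ~interior | (n == 0) | ~np.isfinite(vals)
        mean[bad] = np.nan
        var[bad] = np.nan
        stack.features[f"{band_name}_fo_mean"] = Grid.from_nan(mean, grid)
        stack.features[f"{band_name}_fo_variance"] = Grid.from_nan(var, grid)
    return stack
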