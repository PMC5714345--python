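"""Reusable study experiments over synthetic scenes.

These functions package the parameter-recovery experiments that the analysis
scripts, the test suite and the acceptance script all run: AGB model
recovery on the default scene, driver-importance recovery on coarse scenes
with ~1600 one-km cells, and hotspot-congruence behaviour under congruent
and independent richness.  Problem sizes are chosen so each experiment runs
in seconds to a couple of minutes on one CPU; the coarse driver scenes use
100-m base cells purely to keep the 40 x 40 km extent cheap — effect sizes
and noise levels stay at the generator defaults.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from . import agb as agb_mod
from . import drivers as drivers_mod
from . import richness as richness_mod
from .congruence import SpatialWeights, classify_hotspots, gi_star, overlap_percent, HOT
from .grids import Grid, aggregate, aggregate_circular, euclidean_distance, slope_aspect
from .radarcal import SarScene, calibrate, rfdi, speckle_filter
from .synthscape import (SceneConfig, make_agb_truth, make_bioclim,
                         make_plots, make_ranges, make_sar, make_terrain)
from .texture import TextureConfig, TextureStack, texture_stack

__all__ = [
    "agb_recovery",
    "driver_trial",
    "congruent_overlap",
    "independent_overlap_null",
]


def _sigma0_stack(cfg: SceneConfig, agb_truth: Grid) -> TextureStack:
    hh_dn, hv_dn = make_sar(agb_truth, cfg)
    stack = TextureStack()
    for band, dn in (("hh", hh_dn), ("hv", hv_dn)):
        s = speckle_filter(calibrate(dn), 3, looks=cfg.looks, input_scale="db")
        stack.update(texture_stack(s, TextureConfig(), band))
    return stack


def agb_recovery(config: SceneConfig | None = None, model_seed: int = 0) -> dict:
    """Full AGB-model recovery on one scene: plots -> textures -> rf_fit.

    Returns the fitted model plus its pooled cross-validation metrics and
    the plot table, so callers can also run permutation nulls against the
    same predictors.
    """
    cfg = config or SceneConfig()
    dem, lc, roads, _ = make_terrain(cfg)
    truth = make_agb_truth(dem, lc, roads, cfg)
    plots = make_plots(truth, lc, cfg)
    stack = _sigma0_stack(cfg, truth)
    y = np.array([agb_mod.plot_agb(p) for p in plots])
    table = agb_mod.plot_predictor_table(stack, plots)
    table = table[table.columns[table.notna().all()]]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = agb_mod.rf_fit(table, y, folds=10, seed=model_seed)
    return {"config": cfg, "fit": fit, "table": table, "y": y,
            "stack": stack, "truth": truth}


def _coarse_config(seed: int, **over) -> SceneConfig:
    """40 x 40 km scene on 100-m cells: 1600 one-km cells for the sample."""
    base = dict(n_rows=400, n_cols=400, cell_size=100.0, seed=seed,
                n_species_iucn=25, n_species_endemic=15)
    base.update(over)
    return SceneConfig(**base)


def driver_trial(seed: int, effects: dict | None = None,
                 sample_n: int = 1500, stratum: str = "iucn") -> dict:
    """One driver-importance recovery trial on a coarse synthetic scene.

    Builds the full 12-predictor 1-km stack (AGB truth, aspect, road and
    river distance, altitude, slope, RFDI, landscape diversity and
    fragmentation, and the three bioclim surfaces), rasterizes the species
    ranges into richness, samples ``sample_n`` complete cells and ranks
    importance by the smoother-R^2 procedure.
    """
    over = {"effects": effects} if effects is not None else {}
    cfg = _coarse_config(seed, **over)
    dem, lc, roads, rivers = make_terrain(cfg)
    truth = make_agb_truth(dem, lc, roads, cfg)
    ranges = make_ranges(truth, dem, roads, cfg)
    bioclim = make_bioclim(dem, cfg)

    f = cfg.km_factor
    template = aggregate(truth, f, "mean")
    slope, aspect = slope_aspect(dem)

    hh_dn, hv_dn = make_sar(truth, cfg)
    sar = SarScene(hh_sigma0=speckle_filter(calibrate(hh_dn), 3, cfg.looks, "db"),
                   hv_sigma0=speckle_filter(calibrate(hv_dn), 3, cfg.looks, "db"))
    rfdi_g = rfdi(sar)

    coarse = max(1, f // 5)
    lc_coarse = aggregate(lc, coarse, "majority")
    layers = {
        "altitude": dem,
        "slope": slope,
        "aspect": aspect,
        "rfdi": rfdi_g,
        "landscape_diversity": _km_layer(lc_coarse, template, "diversity"),
        "landscape_fragmentation": _km_layer(lc_coarse, template, "fragmentation"),
        "annual_rainfall": bioclim["annual_rainfall"],
        "mean_temperature": bioclim["mean_temperature"],
        "precip_seasonality": bioclim["precip_seasonality"],
    }
    stack = drivers_mod.build_stack(layers, template, circular=("aspect",))
    stack["agb"] = template
    stack["road_dist"] = euclidean_distance(roads, template)
    stack["river_dist"] = euclidean_distance(rivers, template)

    pam = richness_mod.build_pam(ranges, template)
    flt = richness_mod.iucn_listed if stratum == "iucn" else richness_mod.is_endemic
    richness = richness_mod.richness_grid(pam, flt)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sample = drivers_mod.sample_cells(stack, richness, n=sample_n, seed=seed)
        imp = drivers_mod.rank_importance(sample)
    return {"config": cfg, "importance": imp, "sample": sample,
            "ranges": ranges, "stack": stack, "richness": richness}


def _km_layer(lc_coarse: Grid, template: Grid, which: str) -> Grid:
    from .grids import landscape_diversity, landscape_fragmentation
    fn = landscape_diversity if which == "diversity" else landscape_fragmentation
    return fn(lc_coarse, 5)


def _default_km_weights() -> SpatialWeights:
    return SpatialWeights()


def congruent_overlap(seed: int = 0, shape: tuple = (40, 40),
                      alpha: float = 0.05) -> float:
    """HOT-HOT overlap when richness is a monotone transform of AGB.

    Builds a smooth 1-km AGB-like field, applies a monotone transform as the
    richness layer, and measures the hot-hot union overlap of their Gi*
    classes — congruence should be near total.
    """
    rng = np.random.default_rng(seed)
    from scipy import ndimage
    field = ndimage.gaussian_filter(rng.standard_normal(shape), 3.0)
    field = (field - field.min()) / np.ptp(field) * 300.0 + 20.0
    agb_g = Grid(field, cell_size=1000.0)
    rich = Grid(np.sqrt(field) * 3.0, cell_size=1000.0)  # monotone transform
    w = _default_km_weights()
    cls_a = classify_hotspots(gi_star(agb_g, w), value=agb_g,
                              high_mask_threshold=None, alpha=alpha)
    cls_r = classify_hotspots(gi_star(rich, w), value=rich, alpha=alpha)
    return overlap_percent(cls_a, cls_r, which=HOT, denominator="union")


def independent_overlap_null(seed: int = 0, shape: tuple = (40, 40),
                             alpha: float = 0.05,
                             n_permutations: int = 99) -> dict:
    """Observed hot-hot overlap of two independent fields vs permutation null.

    The richness field is independent of AGB; the null distribution of the
    overlap under no spatial association is built by ``n_permutations``
    toroidal shifts (random rolls in both axes, with random flips) of the
    richness field — a spatial permutation that preserves the field's
    autocorrelation, which cell-wise shuffling would destroy.  Returns the
    observed overlap and the null's 2.5/97.5 percentiles.
    """
    rng = np.random.default_rng(seed)
    from scipy import ndimage

    def smooth_field(r):
        f = ndimage.gaussian_filter(r.standard_normal(shape), 3.0)
        return (f - f.min()) / np.ptp(f)

    agb_g = Grid(smooth_field(rng) * 300.0, cell_size=1000.0)
    rich_vals = smooth_field(rng) * 30.0
    w = _default_km_weights()
    cls_a = classify_hotspots(gi_star(agb_g, w), alpha=alpha)

    def overlap_of(vals):
        cls_r = classify_hotspots(gi_star(Grid(vals, cell_size=1000.0), w),
                                  alpha=alpha)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            v = overlap_percent(cls_a, cls_r, which=HOT, denominator="union")
        return 0.0 if np.isnan(v) else v

    observed = overlap_of(rich_vals)
    null = []
    for _ in range(n_permutations):
        shifted = np.roll(rich_vals,
                          (rng.integers(1, shape[0]), rng.integers(1, shape[1])),
                          axis=(0, 1))
        if rng.random() < 0.5:
            shifted = shifted[::-1]
        if rng.random() < 0.5:
            shifted = shifted[:, ::-1]
        null.append(overlap_of(shifted))
    lo, hi = np.percentile(null, [2.5, 97.5])
    return {"observed": observed, "null_lo": float(lo), "null_hi": float(hi),
            "null_mean": float(np.mean(null))}
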