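"""Synthetic study-landscape generator with known ground truth.

Every downstream stage of the pipeline is tested by parameter recovery on
scenes from this module, which emulates a humid tropical mountain landscape:

* a DEM of smoothed random relief scaled to [0, 1700] m;
* land cover in three classes (primary forest, secondary forest, non-forest)
  driven by road proximity and a smooth disturbance field;
* a latent AGB surface (0-400 Mg/ha) that is high in interior primary forest,
  moderate in secondary forest, near zero outside forest, and mildly
  increasing with road distance;
* L-band HH/HV digital-number grids whose mean backscatter follows a
  saturating curve of AGB (sigma0 = s_max - (s_max - s_min) exp(-AGB/L),
  saturation scale L defaulting to 100 Mg/ha), with gamma-distributed
  multiplicative speckle (equivalent number of looks 4) and an extra
  AGB-dependent fine-scale lognormal term so that *texture* keeps encoding
  biomass where mean backscatter has saturated;
* 36 square 0.25-ha field plots, stratified over the two forest classes,
  whose DBH censuses (all stems >= 30 cm) invert the package's allometry so
  that plot AGB equals local truth times configurable lognormal-ish noise;
* a coarse "global" 1-km AGB raster: truth aggregated, smoothed, biased and
  noised — a degraded oracle for fusion testing;
* bird range polygons assembled from 1-km cells passing species-specific
  habitat rules with configurable effect weights on AGB, elevation, aspect
  and road distance; the drawn weights are recorded per species as ground
  truth for driver-importance recovery;
* smooth synthetic bioclim surfaces (annual rainfall, mean temperature,
  precipitation seasonality) that do not enter the richness rules and hence
  act as known-null predictors.

Everything is deterministic given (config, seed): each generator stage draws
from its own `default_rng([seed, stage_tag])` substream.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import LineString

from . import agb as agb_mod
from .grids import (
    Grid,
    VectorLayer,
    aggregate,
    aggregate_circular,
    euclidean_distance,
    slope_aspect,
    write_grid,
    write_vector,
)
from .richness import SpeciesRange

__all__ = [
    "SceneConfig",
    "Scene",
    "make_terrain",
    "make_agb_truth",
    "make_sar",
    "make_plots",
    "make_global_agb",
    "make_ranges",
    "make_bioclim",
    "make_scene",
    "generate_scene",
]

# land-cover class codes
PRIMARY, SECONDARY, NONFOREST = 1.0, 2.0, 3.0

_STAGE = {"terrain": 1, "agb": 2, "sar": 3, "plots": 4, "global": 5,
          "ranges": 6, "bioclim": 7}


@dataclass
class SceneConfig:
    """Full parameterization of one synthetic scene.

    Defaults describe the study conditions: 25-m base cells over a
    ~31 x 31 km landscape (the 1-km analysis grid is a 40x40 aggregation),
    AGB in 0-400 Mg/ha saturating the radar link at 100 Mg/ha, 36 plots,
    and strong AGB / road-distance effects on bird habitat with weak
    topographic ones.
    """

    n_rows: int = 1240
    n_cols: int = 1240
    cell_size: float = 25.0
    seed: int = 0
    agb_range: tuple = (0.0, 400.0)
    saturation_level: float = 100.0
    n_species_iucn: int = 25
    n_species_endemic: int = 15
    n_plots: int = 36
    plot_noise_cv: float = 0.08         # relative sd of plot AGB vs local truth
    looks: float = 4.0                  # speckle equivalent number of looks
    texture_noise: tuple = (0.04, 0.55) # lognormal sigma = t0 + t1 * AGB/AGBmax
    hv_db_range: tuple = (-22.0, -12.0)
    hh_db_range: tuple = (-13.0, -7.0)
    global_bias: float = 1.1
    global_noise_sd: float = 30.0
    global_smooth_sigma: float = 1.0    # cells of the 1-km grid
    range_noise: float = 0.5            # sd of noise on standardized suitability
    effects: dict = field(default_factory=lambda: {
        "agb": 1.0, "road_dist": 0.8, "elevation": 0.25, "aspect": 0.2})
    terrain_corr_m: float = 3000.0
    agb_corr_m: float = 800.0
    n_roads: int = 3
    n_rivers: int = 2

    def __post_init__(self) -> None:
        lo, hi = self.agb_range
        if not lo < hi:
            raise ValueError("agb_range must satisfy min < max")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STAGE[stage]])

    @property
    def km_factor(self) -> int:
        f = 1000.0 / self.cell_size
        if abs(f - round(f)) > 1e-9:
            raise ValueError("cell_size must divide 1000 m for 1-km aggregation")
        return int(round(f))


@dataclass
class Scene:
    """In-memory bundle of one generated landscape."""

    config: SceneConfig
    dem: Grid
    landcover: Grid
    roads: VectorLayer
    rivers: VectorLayer
    agb_truth: Grid
    hh_dn: Grid
    hv_dn: Grid
    plots: list
    global_agb: Grid
    ranges: list
    bioclim: dict


def _smooth_field(rng: np.random.Generator, shape, sigma_cells: float) -> np.ndarray:
    """Unit-variance smoothed Gaussian random field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma_cells)
    sd = f.std()
    return f / sd if sd > 0 else f


def _crossing_line(rng: np.random.Generator, config: SceneConfig,
                   n_waypoints: int = 7, wiggle: float = 0.15) -> LineString:
    """A polyline crossing the scene edge to edge with lateral jitter."""
    w = config.n_cols * config.cell_size
    h = config.n_rows * config.cell_size
    horizontal = rng.random() < 0.5
    t = np.linspace(0.0, 1.0, n_waypoints)
    lateral = rng.uniform(0.15, 0.85) + rng.normal(0.0, wiggle, n_waypoints).cumsum() / n_waypoints
    lateral = np.clip(lateral, 0.02, 0.98)
    if horizontal:
        xs, ys = t * w, -lateral * h
    else:
        xs, ys = lateral * w, -t * h
    return LineString(np.column_stack([xs, ys]))


def _fast_line_distance(layer: VectorLayer, template: Grid) -> np.ndarray:
    """Cell-resolution distance (m) to polylines via a rasterized EDT.

    Accurate to about one cell — plenty for carving land cover and the AGB
    road effect; the exact vector distance lives in grids.euclidean_distance.
    """
    marks = np.zeros(template.shape, dtype=bool)
    cs = template.cell_size
    for geom in layer.geometries:
        step = cs / 2.0
        n = max(2, int(np.ceil(geom.length / step)) + 1)
        pts = shapely.line_interpolate_point(geom, np.linspace(0.0, geom.length, n))
        xs = shapely.get_x(pts)
        ys = shapely.get_y(pts)
        cc = np.clip(((xs - template.origin_x) / cs).astype(int), 0, template.n_cols - 1)
        rr = np.clip(((template.origin_y - ys) / cs).astype(int), 0, template.n_rows - 1)
        marks[rr, cc] = True
    return ndimage.distance_transform_edt(~marks) * cs


def make_terrain(config: SceneConfig) -> tuple[Grid, Grid, VectorLayer, VectorLayer]:
    """DEM, land cover and road/river polylines for one scene."""
    if config.n_rows < 50 or config.n_cols < 50:
        raise ValueError("degenerate scene: need at least a 50x50 grid")
    rng = config.rng("terrain")
    shape = (config.n_rows, config.n_cols)
    sigma = config.terrain_corr_m / config.cell_size

    relief = _smooth_field(rng, shape, sigma)
    relief = relief - relief.min()
    dem_vals = relief / relief.max() * 1700.0
    dem = Grid(dem_vals, origin_x=0.0, origin_y=0.0, cell_size=config.cell_size)

    roads = VectorLayer([_crossing_line(rng, config) for _ in range(config.n_roads)],
                        [{"road_id": f"R{i}"} for i in range(config.n_roads)])
    rivers = VectorLayer([_crossing_line(rng, config) for _ in range(config.n_rivers)],
                         [{"river_id": f"V{i}"} for i in range(config.n_rivers)])

    road_dist = _fast_line_distance(roads, dem)
    disturb = _smooth_field(rng, shape, sigma / 2.0)
    # clearing along roads, a secondary-forest halo, primary forest elsewhere
    lc = np.full(shape, PRIMARY)
    lc[road_dist < 1200.0 + 600.0 * disturb] = SECONDARY
    lc[road_dist < 350.0 + 150.0 * disturb] = NONFOREST
    landcover = dem.like(lc)
    return dem, landcover, roads, rivers


def make_agb_truth(dem: Grid, landcover: Grid, roads: VectorLayer,
                   config: SceneConfig) -> Grid:
    """Latent AGB surface: forest-class baseline + smooth field + road effect."""
    dem.require_aligned(landcover, "dem/landcover")
    rng = config.rng("agb")
    lc = landcover.values
    lo, hi = config.agb_range
    base = np.where(lc == PRIMARY, 260.0, np.where(lc == SECONDARY, 130.0, 2.0))
    fld = _smooth_field(rng, lc.shape, config.agb_corr_m / config.cell_size)
    road_dist = _fast_line_distance(roads, dem)
    rmax = road_dist.max() or 1.0
    forest = lc != NONFOREST
    vals = base + np.where(forest, 45.0 * fld + 25.0 * road_dist / rmax, 2.0 * fld)
    vals = np.clip(vals, lo, hi)
    vals[~forest] = np.clip(vals[~forest], 0.0, 10.0)
    return dem.like(vals)


def _saturating_db(agb: np.ndarray, db_range: tuple, L: float) -> np.ndarray:
    s_min, s_max = db_range
    return s_max - (s_max - s_min) * np.exp(-agb / L)


def make_sar(agb_truth: Grid, config: SceneConfig) -> tuple[Grid, Grid]:
    """HH/HV digital-number grids encoding AGB in level and in texture.

    Mean sigma0 saturates with AGB; speckle is gamma multiplicative noise in
    linear power; an extra lognormal term whose sigma grows with AGB keeps
    local texture informative beyond saturation.  DN inverts the standard
    calibration: DN = 10**((sigma0 + 83) / 20).
    """
    vals = agb_truth.filled()
    if np.nanmin(vals) < 0:
        raise ValueError("AGB truth must be non-negative")
    rng = config.rng("sar")
    agb_max = config.agb_range[1]
    t0, t1 = config.texture_noise
    sig_tex = t0 + t1 * vals / agb_max

    def one_band(db_range):
        db = _saturating_db(vals, db_range, config.saturation_level)
        power = 10.0 ** (db / 10.0)
        speckle = rng.gamma(config.looks, 1.0 / config.looks, vals.shape)
        texture = np.exp(rng.standard_normal(vals.shape) * sig_tex)
        noisy = power * speckle * texture
        db_noisy = 10.0 * np.log10(noisy)
        dn = 10.0 ** ((db_noisy + 83.0) / 20.0)
        return agb_truth.like(dn)

    hh = one_band(config.hh_db_range)
    hv = one_band(config.hv_db_range)
    return hh, hv


def make_plots(agb_truth: Grid, landcover: Grid, config: SceneConfig,
               margin_cells: int = 3) -> list:
    """Stratified 0.25-ha field plots whose censuses invert the allometry.

    Plot target AGB = local truth * (1 + cv * N(0,1)); DBH values >= 30 cm
    are drawn until the target plot mass is nearly reached and the last stem
    is sized to hit it exactly, so ``plot_agb`` recovers the target to
    numerical precision when the noise is zero.
    """
    agb_truth.require_aligned(landcover, "agb/landcover")
    rng = config.rng("plots")
    lc = landcover.values
    vals = agb_truth.filled()
    coeffs = agb_mod.DEFAULT_ALLOMETRY
    mass30 = float(agb_mod.tree_mass_kg(30.0, coeffs))

    interior = np.zeros(lc.shape, dtype=bool)
    interior[margin_cells:-margin_cells, margin_cells:-margin_cells] = True
    strata = {"primary": PRIMARY, "secondary": SECONDARY}
    counts = {"primary": config.n_plots - config.n_plots // 2,
              "secondary": config.n_plots // 2}
    records = []
    for stratum, code in strata.items():
        cand = np.flatnonzero((lc == code) & interior)
        if cand.size == 0:
            raise ValueError(f"no {stratum}-forest cells available for plots")
        chosen = rng.choice(cand, size=min(counts[stratum], cand.size), replace=False)
        for idx in chosen:
            r, c = np.unravel_index(idx, lc.shape)
            truth = float(vals[r, c])
            target = max(5.0, truth * (1.0 + config.plot_noise_cv * rng.standard_normal()))
            area_ha = 0.25
            target_kg = target * area_ha * 1000.0
            dbh = []
            remaining = target_kg
            while remaining > 2.0 * mass30:
                d = min(30.0 + rng.exponential(18.0), 150.0)
                m = float(agb_mod.tree_mass_kg(d, coeffs))
                if m > remaining - mass30:
                    break
                dbh.append(d)
                remaining -= m
            # last stem absorbs the remainder exactly (>= the census minimum)
            if remaining >= mass30:
                dbh.append(agb_mod.invert_tree_mass(remaining, coeffs))
            elif dbh:
                m_last = float(agb_mod.tree_mass_kg(dbh[-1], coeffs))
                dbh[-1] = agb_mod.invert_tree_mass(m_last + remaining, coeffs)
            else:
                dbh.append(30.0)
            records.append(agb_mod.PlotRecord(
                plot_id=f"P{len(records):03d}",
                x=agb_truth.origin_x + (c + 0.5) * agb_truth.cell_size,
                y=agb_truth.origin_y - (r + 0.5) * agb_truth.cell_size,
                area_ha=area_ha,
                dbh_list=np.asarray(dbh),
                stratum=stratum,
            ))
    return records


def make_global_agb(agb_truth: Grid, config: SceneConfig) -> Grid:
    """Degraded 1-km oracle: aggregate, smooth, bias, noise."""
    agg = aggregate(agb_truth, config.km_factor, "mean")
    vals = agg.filled()
    if config.global_smooth_sigma > 0:
        vals = ndimage.gaussian_filter(vals, config.global_smooth_sigma)
    rng = config.rng("global")
    vals = vals * config.global_bias
    if config.global_noise_sd > 0:
        vals = vals + rng.normal(0.0, config.global_noise_sd, vals.shape)
    vals = np.maximum(vals, 0.0)
    return agg.like(vals)


def _km_template(config: SceneConfig, like: Grid) -> Grid:
    return aggregate(like, config.km_factor, "mean")


def make_ranges(agb_truth: Grid, dem: Grid, roads: VectorLayer,
                config: SceneConfig) -> list:
    """Species range polygons from habitat rules on 1-km layers.

    Per species the suitability is a weighted sum of standardized 1-km AGB,
    road distance, elevation and an aspect preference term plus noise; cells
    above a species-specific quantile form the range (union of cell boxes).
    AGB and road-distance weights are drawn positive around the configured
    effect sizes; elevation and aspect weights carry random signs.  The drawn
    weights are stored on each :class:`SpeciesRange` as recovery ground truth.
    """
    rng = config.rng("ranges")
    f = config.km_factor
    agb1 = aggregate(agb_truth, f, "mean")
    elev1 = aggregate(dem, f, "mean")
    _, aspect = slope_aspect(dem)
    aspect1 = aggregate_circular(aspect, f)
    road1 = euclidean_distance(roads, agb1)

    def z(g: Grid) -> np.ndarray:
        v = g.filled()
        mu, sd = np.nanmean(v), np.nanstd(v)
        return (v - mu) / (sd if sd > 0 else 1.0)

    z_agb, z_elev, z_road = z(agb1), z(elev1), z(road1)
    aspect_rad = np.deg2rad(aspect1.filled())
    shape = z_agb.shape
    cs = agb1.cell_size
    xs = agb1.origin_x + np.arange(shape[1]) * cs
    ys = agb1.origin_y - np.arange(shape[0]) * cs
    xx, yy = np.meshgrid(xs, ys)

    species: list[SpeciesRange] = []
    groups = [("IUCN", config.n_species_iucn, False),
              ("END", config.n_species_endemic, True)]
    for prefix, count, endemic in groups:
        for k in range(count):
            eff = config.effects
            for attempt in range(11):
                w_agb = eff["agb"] * abs(rng.normal(1.0, 0.3))
                w_road = eff["road_dist"] * abs(rng.normal(1.0, 0.3))
                w_elev = eff["elevation"] * rng.normal(0.0, 1.0)
                w_aspect = eff["aspect"] * rng.normal(0.0, 1.0)
                theta = rng.uniform(0.0, 2 * np.pi)
                asp_term = np.cos(aspect_rad - theta)
                asp_term = np.where(np.isfinite(asp_term), asp_term, 0.0)
                suit = (w_agb * z_agb + w_road * z_road + w_elev * z_elev
                        + w_aspect * asp_term
                        + config.range_noise * rng.standard_normal(shape))
                frac = rng.uniform(0.15, 0.5)
                thresh = np.nanquantile(suit, 1.0 - frac)
                cells = np.flatnonzero((suit >= thresh).ravel())
                if cells.size:
                    break
                if attempt == 9:
                    warnings.warn(f"species {prefix}{k}: empty range after 10 tries")
            rr, cc = np.unravel_index(cells, shape)
            boxes = shapely.box(xx[rr, cc], yy[rr, cc] - cs,
                                xx[rr, cc] + cs, yy[rr, cc])
            geom = shapely.unary_union(boxes)
            if endemic:
                status = rng.choice(["LC", "NT", "VU"], p=[0.6, 0.25, 0.15])
            else:
                status = rng.choice(["CR", "EN", "VU", "NT"], p=[0.1, 0.2, 0.35, 0.35])
            species.append(SpeciesRange(
                species_id=f"{prefix}{k:03d}",
                geometry=geom,
                iucn_status=str(status),
                endemic=endemic,
                effects={"agb": w_agb, "road_dist": w_road,
                         "elevation": w_elev, "aspect": w_aspect},
            ))
    return species


def make_bioclim(dem: Grid, config: SceneConfig) -> dict:
    """Smooth synthetic climate surfaces (null predictors for the drivers).

    Temperature follows a lapse rate off the DEM plus smooth noise; rainfall
    and seasonality are independent smooth gradients.
    """
    rng = config.rng("bioclim")
    shape = dem.shape
    sigma = config.terrain_corr_m / config.cell_size
    xnorm = np.linspace(0.0, 1.0, shape[1])[None, :] * np.ones((shape[0], 1))
    ynorm = np.linspace(0.0, 1.0, shape[0])[:, None] * np.ones((1, shape[1]))
    rain = 1600.0 + 1400.0 * (0.5 * xnorm + 0.3 * ynorm
                              + 0.2 * _smooth_field(rng, shape, sigma))
    rain = np.clip(rain, 1200.0, 3200.0)
    temp = 27.0 - 6.5 * dem.filled() / 1000.0 + 0.3 * _smooth_field(rng, shape, sigma)
    season = 40.0 + 15.0 * _smooth_field(rng, shape, sigma)
    return {
        "annual_rainfall": dem.like(rain),
        "mean_temperature": dem.like(temp),
        "precip_seasonality": dem.like(season),
    }


def make_scene(config: SceneConfig) -> Scene:
    """Generate the full, internally consistent landscape in memory."""
    dem, landcover, roads, rivers = make_terrain(config)
    agb_truth = make_agb_truth(dem, landcover, roads, config)
    hh_dn, hv_dn = make_sar(agb_truth, config)
    plots = make_plots(agb_truth, landcover, config)
    global_agb = make_global_agb(agb_truth, config)
    ranges = make_ranges(agb_truth, dem, roads, config)
    bioclim = make_bioclim(dem, config)
    return Scene(config=config, dem=dem, landcover=landcover, roads=roads,
                 rivers=rivers, agb_truth=agb_truth, hh_dn=hh_dn, hv_dn=hv_dn,
                 plots=plots, global_agb=global_agb, ranges=ranges,
                 bioclim=bioclim)


def generate_scene(config: SceneConfig, out_dir) -> list:
    """Write a full scene to disk; returns the list of files written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scene = make_scene(config)
    written = []

    rasters = {
        "dem.tif": scene.dem,
        "landcover.tif": scene.landcover,
        "agb_truth.tif": scene.agb_truth,
        "hh_dn.tif": scene.hh_dn,
        "hv_dn.tif": scene.hv_dn,
        "global_agb.tif": scene.global_agb,
        "annual_rainfall.tif": scene.bioclim["annual_rainfall"],
        "mean_temperature.tif": scene.bioclim["mean_temperature"],
        "precip_seasonality.tif": scene.bioclim["precip_seasonality"],
    }
    for name, grid in rasters.items():
        write_grid(grid, out / name)
        written.append(name)

    write_vector(scene.roads, out / "roads.geojson")
    write_vector(scene.rivers, out / "rivers.geojson")
    written += ["roads.geojson", "rivers.geojson"]

    with open(out / "plots.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["plot_id", "x", "y", "area_ha", "stratum"])
        for p in scene.plots:
            w.writerow([p.plot_id, f"{p.x:.3f}", f"{p.y:.3f}", p.area_ha, p.stratum])
    with open(out / "trees.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["plot_id", "dbh_cm"])
        for p in scene.plots:
            for d in p.dbh_list:
                w.writerow([p.plot_id, f"{d:.6f}"])
    written += ["plots.csv", "trees.csv"]

    ranges_layer = VectorLayer(
        [sp.geometry for sp in scene.ranges],
        [{"species_id": sp.species_id, "iucn_status": sp.iucn_status,
          "endemic": sp.endemic} for sp in scene.ranges],
    )
    write_vector(ranges_layer, out / "ranges.geojson")
    written.append("ranges.geojson")

    truth = {
        "config": {k: v for k, v in asdict(config).items()},
        "species_effects": {sp.species_id: sp.effects for sp in scene.ranges},
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    written.append("truth.json")
    return written
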