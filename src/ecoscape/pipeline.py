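"""End-to-end orchestration of the synthetic study.

``run_all`` executes the seven stages in order — scene generation, SAR
calibration, texture extraction, AGB modelling (fit, predict, fuse),
richness rasterization, driver analysis, and congruence — writing every
intermediate artifact under the output directory plus a ``manifest.json``
with the config hash, seed, per-stage file checksums and timings.  A rerun
with the same config skips stages whose recorded outputs are intact, so
deleting one stage's directory re-executes only that stage and those after
it that read its outputs afresh (each stage reads its inputs from disk).

One master seed fans out to the generator's per-stage substreams and to the
model fits, so (config, seed) fully determines every numeric artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import agb as agb_mod
from . import drivers as drivers_mod
from . import richness as richness_mod
from .congruence import SpatialWeights, congruence_report
from .grids import (Grid, aggregate, aggregate_circular, euclidean_distance,
                    landscape_diversity, landscape_fragmentation, read_grid,
                    read_vector, slope_aspect, write_grid)
from .radarcal import SarScene, calibrate, rfdi, speckle_filter
from .synthscape import SceneConfig, generate_scene
from .texture import TextureConfig, TextureStack, texture_stack

__all__ = ["RunConfig", "run_all", "STAGES", "run_stage"]

log = logging.getLogger("ecoscape")


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    texture: TextureConfig = field(default_factory=TextureConfig)
    weights: SpatialWeights = field(default_factory=SpatialWeights)
    alpha: float = 0.05
    agb_high_threshold: float = 180.0
    sample_n: int = 1500
    folds: int = 10
    kernel_sizes: tuple = (4, 8, 16)
    landcover_metric_window: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        # the master seed governs the scene too
        self.scene.seed = int(self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, sub in (("scene", SceneConfig), ("texture", TextureConfig),
                         ("weights", SpatialWeights)):
            if key in d and isinstance(d[key], dict):
                subknown = {f.name for f in dataclasses.fields(sub)}
                bad = set(d[key]) - subknown
                if bad:
                    raise ValueError(f"unknown {key} config keys: {sorted(bad)}")
                if key == "texture" and "offsets" in d[key]:
                    d[key]["offsets"] = tuple(map(tuple, d[key]["offsets"]))
                if key == "scene":
                    for tup in ("agb_range", "texture_noise", "hv_db_range",
                                "hh_db_range"):
                        if tup in d[key]:
                            d[key][tup] = tuple(d[key][tup])
                d[key] = sub(**d[key])
        if "kernel_sizes" in d:
            d["kernel_sizes"] = tuple(d["kernel_sizes"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Stage implementations.  Each reads its inputs from prior stage directories
# and returns the list of files (relative to out root) it wrote.
# ---------------------------------------------------------------------------

def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"missing required input artifact: {path}")
    return path


def stage_generate(cfg: RunConfig, out: Path) -> list:
    d = out / "scene"
    files = generate_scene(cfg.scene, d)
    return [f"scene/{f}" for f in files]


def stage_calibrate(cfg: RunConfig, out: Path) -> list:
    d = out / "calibrate"
    d.mkdir(parents=True, exist_ok=True)
    written = []
    sigma = {}
    for band in ("hh", "hv"):
        dn = read_grid(_require(out / "scene" / f"{band}_dn.tif"))
        cal = calibrate(dn)
        filt = speckle_filter(cal, window=3, looks=cfg.scene.looks,
                              input_scale="db")
        sigma[band] = filt
        write_grid(filt, d / f"{band}_sigma0.tif")
        written.append(f"calibrate/{band}_sigma0.tif")
    scene_sar = SarScene(hh_sigma0=sigma["hh"], hv_sigma0=sigma["hv"])
    write_grid(rfdi(scene_sar), d / "rfdi.tif")
    written.append("calibrate/rfdi.tif")
    return written


def stage_texturize(cfg: RunConfig, out: Path) -> list:
    d = out / "texture"
    d.mkdir(parents=True, exist_ok=True)
    written = []
    for band in ("hh", "hv"):
        grid = read_grid(_require(out / "calibrate" / f"{band}_sigma0.tif"))
        stack = texture_stack(grid, cfg.texture, band_name=band)
        for name, g in stack.features.items():
            write_grid(g, d / f"{name}.tif")
            written.append(f"texture/{name}.tif")
    return written


def _load_texture_stack(out: Path) -> TextureStack:
    stack = TextureStack()
    for path in sorted((out / "texture").glob("*.tif")):
        stack.features[path.stem] = read_grid(path)
    if not stack.features:
        raise FileNotFoundError(f"missing required input artifacts in {out / 'texture'}")
    return stack


def _read_plots(out: Path) -> list:
    plots = pd.read_csv(_require(out / "scene" / "plots.csv"))
    trees = pd.read_csv(_require(out / "scene" / "trees.csv"))
    records = []
    for _, row in plots.iterrows():
        dbh = trees.loc[trees.plot_id == row.plot_id, "dbh_cm"].to_numpy()
        records.append(agb_mod.PlotRecord(
            plot_id=row.plot_id, x=row.x, y=row.y, area_ha=row.area_ha,
            dbh_list=dbh, stratum=row.stratum))
    return records


def stage_fit_agb(cfg: RunConfig, out: Path) -> list:
    d = out / "agb"
    d.mkdir(parents=True, exist_ok=True)
    stack = _load_texture_stack(out)
    records = _read_plots(out)
    y = np.array([agb_mod.plot_agb(p) for p in records])

    table = agb_mod.plot_predictor_table(stack, records)
    keep = table.columns[table.notna().all()]
    table = table[keep]

    fit = agb_mod.rf_fit(table, y, folds=cfg.folds, seed=cfg.seed)
    pred = agb_mod.predict_map(fit, stack)
    write_grid(pred, d / "agb_pred.tif")

    pred_1km = aggregate(pred, cfg.scene.km_factor, "mean")
    write_grid(pred_1km, d / "agb_pred_1km.tif")
    global_agb = read_grid(_require(out / "scene" / "global_agb.tif"))
    fused, weight = agb_mod.fuse_maps(pred_1km, global_agb, cfg.kernel_sizes)
    write_grid(fused, d / "fused_1km.tif")
    write_grid(weight, d / "fusion_weight_1km.tif")

    report = {
        "retained_predictors": fit.retained_predictors,
        "max_features": fit.max_features,
        "cv_metrics": fit.cv_metrics,
        "importance": fit.importance,
        "plot_agb": y.tolist(),
        "cv_predictions": fit.cv_predictions.tolist(),
    }
    with open(d / "fit_report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return [f"agb/{n}" for n in ("agb_pred.tif", "agb_pred_1km.tif",
                                 "fused_1km.tif", "fusion_weight_1km.tif",
                                 "fit_report.json")]


def stage_richness(cfg: RunConfig, out: Path) -> list:
    d = out / "richness"
    d.mkdir(parents=True, exist_ok=True)
    layer = read_vector(_require(out / "scene" / "ranges.geojson"))
    ranges = [richness_mod.SpeciesRange(
        species_id=a["species_id"], geometry=g,
        iucn_status=a["iucn_status"], endemic=bool(a["endemic"]))
        for g, a in zip(layer.geometries, layer.attributes)]
    template = aggregate(read_grid(_require(out / "scene" / "agb_truth.tif")),
                         cfg.scene.km_factor, "mean")
    pam = richness_mod.build_pam(ranges, template)
    for name, flt in (("iucn", richness_mod.iucn_listed),
                      ("endemic", richness_mod.is_endemic)):
        write_grid(richness_mod.richness_grid(pam, flt),
                   d / f"richness_{name}.tif")
    xx, yy = template.cell_centers()
    pam_df = pd.DataFrame(pam.matrix,
                          columns=[sp.species_id for sp in pam.species])
    pam_df.insert(0, "y", yy.ravel())
    pam_df.insert(0, "x", xx.ravel())
    pam_df.insert(0, "cell_id", np.arange(pam.matrix.shape[0]))
    pam_df.to_csv(d / "pam.csv", index=False)
    return ["richness/richness_iucn.tif", "richness/richness_endemic.tif",
            "richness/pam.csv"]


def _driver_stack(cfg: RunConfig, out: Path) -> dict:
    dem = read_grid(_require(out / "scene" / "dem.tif"))
    landcover = read_grid(_require(out / "scene" / "landcover.tif"))
    fused = read_grid(_require(out / "agb" / "fused_1km.tif"))
    rfdi_g = read_grid(_require(out / "calibrate" / "rfdi.tif"))
    slope, aspect = slope_aspect(dem)
    template = fused

    roads = read_vector(_require(out / "scene" / "roads.geojson"))
    rivers = read_vector(_require(out / "scene" / "rivers.geojson"))
    road_dist = euclidean_distance(roads, template)
    river_dist = euclidean_distance(rivers, template)

    # landscape metrics on a ~200-m majority land-cover product, then to 1 km
    coarse_factor = max(1, cfg.scene.km_factor // 5)
    lc_coarse = aggregate(landcover, coarse_factor, "majority")
    w = cfg.landcover_metric_window
    diversity = landscape_diversity(lc_coarse, w)
    fragmentation = landscape_fragmentation(lc_coarse, w)

    layers = {
        "altitude": dem,
        "slope": slope,
        "aspect": aspect,
        "rfdi": rfdi_g,
        "landscape_diversity": diversity,
        "landscape_fragmentation": fragmentation,
        "annual_rainfall": read_grid(_require(out / "scene" / "annual_rainfall.tif")),
        "mean_temperature": read_grid(_require(out / "scene" / "mean_temperature.tif")),
        "precip_seasonality": read_grid(_require(out / "scene" / "precip_seasonality.tif")),
    }
    stack = drivers_mod.build_stack(layers, template, circular=("aspect",))
    stack["agb"] = fused
    stack["road_dist"] = road_dist
    stack["river_dist"] = river_dist
    return stack


def stage_drivers(cfg: RunConfig, out: Path) -> list:
    d = out / "drivers"
    d.mkdir(parents=True, exist_ok=True)
    stack = _driver_stack(cfg, out)
    written = []
    for stratum in ("iucn", "endemic"):
        richness = read_grid(_require(out / "richness" / f"richness_{stratum}.tif"))
        sample = drivers_mod.sample_cells(stack, richness, n=cfg.sample_n,
                                          seed=cfg.seed)
        svr = drivers_mod.svr_fit(sample, folds=cfg.folds, seed=cfg.seed)
        imp = drivers_mod.rank_importance(sample)
        surrogate = drivers_mod.rf_surrogate(sample, seed=cfg.seed)

        pd.DataFrame({
            "predictor": list(imp.scores),
            "score": [imp.scores[k] for k in imp.scores],
            "raw_r2": [imp.raw_r2[k] for k in imp.scores],
        }).sort_values("score", ascending=False).to_csv(
            d / f"importance_{stratum}.csv", index=False)

        curves = []
        for name in imp.ranked()[:6]:
            xg, yg = drivers_mod.partial_dependence(surrogate, sample, name)
            curves.append(pd.DataFrame({"predictor": name, "x": xg, "yhat": yg}))
        pd.concat(curves).to_csv(d / f"pd_curves_{stratum}.csv", index=False)

        dirs = {name: drivers_mod.direction_of_effect(sample, name)
                for name in sample.X.columns}
        pd.DataFrame([
            {"predictor": k, **v} for k, v in dirs.items()
        ]).to_csv(d / f"directions_{stratum}.csv", index=False)

        sample.X.assign(richness=sample.y, cell=sample.cells).to_csv(
            d / f"sample_{stratum}.csv", index=False)
        with open(d / f"svr_{stratum}.json", "w") as fh:
            json.dump({"cv_r2": svr.cv_r2, "params": svr.params}, fh, indent=1)
        written += [f"drivers/{n}_{stratum}.{e}" for n, e in (
            ("importance", "csv"), ("pd_curves", "csv"), ("directions", "csv"),
            ("sample", "csv"), ("svr", "json"))]
    return written


def stage_congruence(cfg: RunConfig, out: Path) -> list:
    d = out / "congruence"
    d.mkdir(parents=True, exist_ok=True)
    fused = read_grid(_require(out / "agb" / "fused_1km.tif"))
    r_iucn = read_grid(_require(out / "richness" / "richness_iucn.tif"))
    r_end = read_grid(_require(out / "richness" / "richness_endemic.tif"))
    report = congruence_report(fused, r_iucn, r_end, weights=cfg.weights,
                               alpha=cfg.alpha,
                               agb_high_threshold=cfg.agb_high_threshold)
    written = []
    for name in report.classes:
        write_grid(report.classes[name], d / f"class_{name}.tif")
        write_grid(report.z[name], d / f"z_{name}.tif")
        written += [f"congruence/class_{name}.tif", f"congruence/z_{name}.tif"]
    with open(d / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=1)
    written.append("congruence/report.json")
    return written


STAGES = [
    ("generate", stage_generate),
    ("calibrate", stage_calibrate),
    ("texturize", stage_texturize),
    ("fit-agb", stage_fit_agb),
    ("richness", stage_richness),
    ("drivers", stage_drivers),
    ("congruence", stage_congruence),
]


def run_stage(name: str, cfg: RunConfig, out_dir) -> list:
    """Run one named stage standalone on prior stage outputs."""
    funcs = dict(STAGES)
    if name not in funcs:
        raise ValueError(f"unknown stage {name!r}; choose from {list(funcs)}")
    return funcs[name](cfg, Path(out_dir))


def run_all(cfg: RunConfig, out_dir, resume: bool = True) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    prior = {}
    if resume and manifest_path.exists():
        with open(manifest_path) as fh:
            old = json.load(fh)
        if old.get("config_hash") == cfg.hash():
            prior = old.get("stages", {})

    manifest = {"config_hash": cfg.hash(), "seed": cfg.seed, "stages": {}}
    for name, func in STAGES:
        rec = prior.get(name)
        if rec:
            intact = all((out / f).exists() and _sha256(out / f) == h
                         for f, h in rec["outputs"].items())
            if intact:
                log.info("stage %s: outputs intact, skipping", name)
                manifest["stages"][name] = {**rec, "skipped": True}
                continue
        log.info("stage %s: running", name)
        t0 = time.perf_counter()
        try:
            files = func(cfg, out)
        except Exception as exc:
            log.error("stage %s failed: %s", name, exc)
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        elapsed = time.perf_counter() - t0
        manifest["stages"][name] = {
            "outputs": {f: _sha256(out / f) for f in files},
            "elapsed_s": round(elapsed, 3),
            "skipped": False,
        }
        log.info("stage %s: done in %.1f s (%d files)", name, elapsed, len(files))
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=1)
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
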