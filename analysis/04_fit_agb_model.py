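"""Fit the plot-to-texture biomass model and fuse local/global maps.

36 field plots (DBH-only allometry) against the texture stack: correlation
screening at |r| >= 0.75, random forest with 10-fold CV, OOB permutation
importance, wall-to-wall prediction, and kernel-correlation fusion with the
coarse global AGB raster.
"""

import json

import numpy as np

from _common import RUN_DIR, publish, run_config
from ecoscape.grids import read_grid
from ecoscape.pipeline import run_stage

cfg = run_config()
run_stage("fit-agb", cfg, RUN_DIR)

rep = json.load(open(RUN_DIR / "agb" / "fit_report.json"))
m = rep["cv_metrics"]
print(f"cross-validated fit over {len(rep['plot_agb'])} plots:")
print(f"  r = {m['r']:.2f}, RMSE = {m['rmse']:.1f} Mg/ha, "
      f"MAE = {m['mae']:.1f} Mg/ha, %bias = {m['pct_bias']:.1f}")
print("retained predictors and OOB importance:")
for name, score in sorted(rep["importance"].items(), key=lambda kv: -kv[1]):
    print(f"  {name:20s} {score:6.1f}")

pred = read_grid(RUN_DIR / "agb" / "agb_pred.tif").filled()
fused = read_grid(RUN_DIR / "agb" / "fused_1km.tif").filled()
glob = read_grid(RUN_DIR / "scene" / "global_agb.tif").filled()
print(f"predicted AGB {np.nanmin(pred):.0f}-{np.nanmax(pred):.0f} Mg/ha; "
      f"global map {np.nanmin(glob):.0f}-{np.nanmax(glob):.0f}; "
      f"fused {np.nanmin(fused):.0f}-{np.nanmax(fused):.0f}")
publish("agb/fit_report.json")
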