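"""Extract moving-window GLCM texture features from both SAR bands.

Eight Haralick statistics plus first-order mean/variance per band, 32 grey
levels over a 5x5 window — the predictor stack for the biomass model.
"""

import numpy as np

from _common import RUN_DIR, run_config
from ecoscape.grids import read_grid
from ecoscape.pipeline import run_stage

cfg = run_config()
files = run_stage("texturize", cfg, RUN_DIR)
print(f"wrote {len(files)} texture rasters")

truth = read_grid(RUN_DIR / "scene" / "agb_truth.tif").filled()
print("correlation of each HV texture with AGB truth (sampled):")
rng = np.random.default_rng(0)
idx = rng.choice(truth.size, 20000, replace=False)
for name in ("hv_fo_mean", "hv_fo_variance", "hv_homogeneity",
             "hv_second_moment", "hv_contrast"):
    t = read_grid(RUN_DIR / "texture" / f"{name}.tif").filled().ravel()[idx]
    a = truth.ravel()[idx]
    ok = np.isfinite(t) & np.isfinite(a)
    r = np.corrcoef(t[ok], a[ok])[0, 1]
    print(f"  {name:20s} r = {r:+.2f}")
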