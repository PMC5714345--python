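"""Generate the synthetic study landscape.

Writes the full scene (DEM, land cover, SAR digital numbers, latent AGB
truth, degraded global AGB, roads/rivers, field plots, species ranges) to
the shared run directory and summarizes what the landscape looks like.
"""

import numpy as np

from _common import RUN_DIR, run_config
from ecoscape.pipeline import run_stage
from ecoscape.grids import read_grid

cfg = run_config()
files = run_stage("generate", cfg, RUN_DIR)
print(f"wrote {len(files)} scene files under {RUN_DIR / 'scene'}")

dem = read_grid(RUN_DIR / "scene" / "dem.tif")
truth = read_grid(RUN_DIR / "scene" / "agb_truth.tif")
lc = read_grid(RUN_DIR / "scene" / "landcover.tif")
print(f"scene: {dem.n_rows} x {dem.n_cols} cells at {dem.cell_size:.0f} m "
      f"({dem.n_rows * dem.cell_size / 1000:.0f} km extent)")
print(f"elevation 0-{dem.values.max():.0f} m; "
      f"AGB truth {truth.values.min():.0f}-{truth.values.max():.0f} Mg/ha")
for code, name in ((1, "primary forest"), (2, "secondary forest"),
                   (3, "non-forest")):
    frac = np.mean(lc.values == code)
    print(f"  {name}: {100 * frac:.1f}% of the scene, "
          f"mean AGB {truth.values[lc.values == code].mean():.0f} Mg/ha")
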