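"""Rasterize bird range polygons into 1-km richness grids.

A presence-absence matrix over the 1-km grid, summed within the IUCN-listed
(CR/EN/VU/NT) and endemic strata.
"""

import numpy as np

from _common import RUN_DIR, run_config
from ecoscape.grids import read_grid
from ecoscape.pipeline import run_stage

cfg = run_config()
run_stage("richness", cfg, RUN_DIR)

for stratum in ("iucn", "endemic"):
    g = read_grid(RUN_DIR / "richness" / f"richness_{stratum}.tif")
    v = g.values
    print(f"{stratum:8s}: richness {v.min():.0f}-{v.max():.0f} species "
          f"per km^2 (mean {v.mean():.1f}) over {v.size} cells")
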