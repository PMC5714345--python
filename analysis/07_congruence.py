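"""Hotspot congruence between AGB and richness at 1 km.

Getis-Ord Gi* hot/coldspots (fixed 3-km band, alpha 0.05, AGB hotspots also
above 180 Mg/ha), percent area overlaps under four denominator conventions,
and Pearson correlations with Dutilleul-corrected degrees of freedom.
"""

import json

from _common import RUN_DIR, publish, run_config
from ecoscape.pipeline import run_stage

cfg = run_config()
run_stage("congruence", cfg, RUN_DIR)

rep = json.load(open(RUN_DIR / "congruence" / "report.json"))
print("percent area overlap with AGB clusters (union denominator):")
for stratum in ("iucn", "endemic"):
    hot = rep["overlaps"][f"{stratum}|hot|union"]
    cold = rep["overlaps"][f"{stratum}|cold|union"]
    print(f"  {stratum:8s} hot-hot {hot:5.1f}%   cold-cold {cold:5.1f}%")
print("corrected correlations:")
for stratum, c in rep["correlations"].items():
    print(f"  AGB vs {stratum:8s} r = {c['r']:+.2f}, effective df "
          f"{c['effective_df']:.1f} of n = {c['n']}, p = {c['p']:.3g}")
publish("congruence/report.json")
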