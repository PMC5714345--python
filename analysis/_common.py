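"""Shared run configuration for the numbered analysis scripts.

All scripts drive the same pipeline run directory so each step builds on the
previous one.  Large rasters stay under scratch/; small tables and reports
are copied into results/.
"""

from pathlib import Path

from ecoscape.pipeline import RunConfig

ROOT = Path(__file__).resolve().parents[1]
RUN_DIR = ROOT / "scratch" / "analysis_run"
RESULTS = ROOT / "results"


def run_config(seed: int = 0) -> RunConfig:
    return RunConfig(seed=seed)


def publish(*relpaths: str) -> None:
    """Copy small text artifacts from the run directory into results/."""
    RESULTS.mkdir(exist_ok=True)
    for rel in relpaths:
        src = RUN_DIR / rel
        dest = RESULTS / src.name
        dest.write_bytes(src.read_bytes())
        print(f"  -> results/{dest.name}")
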