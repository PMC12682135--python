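"""Shared locations for the numbered analysis scripts.

Each script imports this module to agree on where the simulated cohort
lives and where derived artifacts go.  Everything is relative to the
repository root so the scripts can be run from any working directory:

    python analysis/01_simulate_cohort.py
"""

from pathlib import Path

from ctdna_kinetics.pipeline import RunConfig

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
COHORT_DIR = RESULTS / "cohort"
ANALYSIS_DIR = RESULTS / "analysis"

COHORT_SEED = 20260  # fixes the simulated trial reproduced in the README


def run_config() -> RunConfig:
    return RunConfig(
        droplets_csv=str(COHORT_DIR / "droplets.csv"),
        manifest_csv=str(COHORT_DIR / "manifest.csv"),
        clinical_csv=str(COHORT_DIR / "clinical.csv"),
        imaging_csv=str(COHORT_DIR / "imaging.csv"),
        outdir=str(ANALYSIS_DIR),
        seed=COHORT_SEED,
    )
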