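"""Assign the day-60-to-122 landmark ctDNA status to each patient.

Writes results/analysis/landmark.csv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _paths import run_config

from ctdna_kinetics.pipeline import run_landmark


def main() -> None:
    cfg = run_config()
    path = run_landmark(cfg)
    lm = pd.read_csv(path)
    counts = lm["landmark_status"].value_counts()
    lo, hi = cfg.window_days
    print(f"landmark window: days {lo:.0f}-{hi:.0f} after treatment start")
    for status, n in counts.items():
        print(f"  {status}: {n}")


if __name__ == "__main__":
    main()
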