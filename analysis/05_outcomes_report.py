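"""Survival stratified by ctDNA status plus baseline associations.

Writes results/analysis/{survival_summary.json,km_curves.csv,
correlations.csv,patient_series.csv} and prints the headline numbers.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _paths import run_config

from ctdna_kinetics.pipeline import run_report


def _fmt_months(v) -> str:
    return "not reached" if v is None else f"{v:.1f} mo"


def main() -> None:
    cfg = run_config()
    paths = run_report(cfg)
    summary = json.loads(Path(paths["survival_summary"]).read_text())
    for key in ("baseline_os", "baseline_pfs", "landmark_os", "landmark_pfs"):
        block = summary[key]
        if "error" in block:
            print(f"{key}: not computed ({block['error']})")
            continue
        print(f"{key}: median positive {_fmt_months(block['median_positive_months'])}"
              f" vs negative {_fmt_months(block['median_negative_months'])},"
              f" log-rank p = {block['logrank_p']:.3f}"
              f" (n = {block['n_positive']} vs {block['n_negative']})")
    corr = pd.read_csv(paths["correlations"])
    print("\nbaseline associations of ctDNA MAF:")
    print(corr.to_string(index=False))


if __name__ == "__main__":
    main()
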