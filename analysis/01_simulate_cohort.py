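"""Simulate the 18-patient monitoring cohort and write its raw tables.

Produces results/cohort/{droplets,manifest,clinical,imaging}.csv and
truth.json (generator ground truth, used only for validation figures).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _paths import COHORT_DIR, COHORT_SEED

from ctdna_kinetics.simulate import CohortParams, simulate_cohort


def main() -> None:
    params = CohortParams(seed=COHORT_SEED)
    sim = simulate_cohort(params)
    paths = sim.write(COHORT_DIR)
    n_draws = len(sim.manifest)
    n_wells = len(sim.droplets)
    print(f"simulated {params.n_patients} patients, {n_draws} plasma draws, "
          f"{n_wells} ddPCR wells (seed {COHORT_SEED})")
    for name, path in sorted(paths.items()):
        print(f"  {name}: {path}")


if __name__ == "__main__":
    main()
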