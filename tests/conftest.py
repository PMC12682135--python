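import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/util importable

from ctdna_kinetics.pipeline import quantify_droplets
from ctdna_kinetics.simulate import CohortParams, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded cohort at the default study conditions (18 patients)."""
    return simulate_cohort(CohortParams(seed=20260))


@pytest.fixture(scope="session")
def quantified(default_cohort):
    maf, meta = quantify_droplets(default_cohort.droplets, default_cohort.manifest)
    return maf, meta
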