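import logging

import pytest

from longiplasma.normalization import normalize_pipeline
from longiplasma.synthetic_data import SimConfig, simulate_cohort

logging.getLogger("longiplasma").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort (30 individuals x 60 proteins) with every planted
    structure active; shared across tests that only need plausible data."""
    cfg = SimConfig(n_individuals=30, n_proteins=60, n_snps=300,
                    n_cis_effects=3, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_normalized(small_cohort):
    ds, gm, traits, gt = small_cohort
    norm, audit = normalize_pipeline(ds)
    return norm, audit


@pytest.fixture(scope="session")
def default_cohort():
    """The full emulated study design: 101 individuals x 4 visits x 200
    proteins with duplicate assays, plates, modules, cis effects."""
    return simulate_cohort(SimConfig(seed=5))


@pytest.fixture(scope="session")
def default_normalized(default_cohort):
    ds, gm, traits, gt = default_cohort
    norm, audit = normalize_pipeline(ds)
    return norm, audit
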