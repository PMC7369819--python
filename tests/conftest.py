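import numpy as np
import pandas as pd
import pytest

from methmediate.deconvolution import estimate_cell_proportions
from methmediate.synthetic_data import simulate_cohort, strong_effects_config


@pytest.fixture(scope="session")
def strong_cohort():
    """One clearly-signaled cohort shared by read-only tests."""
    return simulate_cohort(strong_effects_config(n_samples=2000, seed=11))


@pytest.fixture(scope="session")
def strong_samples(strong_cohort):
    props = estimate_cell_proportions(strong_cohort.betas, strong_cohort.reference)
    return strong_cohort.samples.with_cell_proportions(props.data)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
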