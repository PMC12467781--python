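"""Shared fixtures: small seeded cohorts that keep the suite fast."""

import numpy as np
import pytest

import serscreen as ss
from serscreen.preprocess import preprocess_records


@pytest.fixture(scope="session")
def small_config():
    """3 groups × 4 samples × 3 replicates with the default effect profiles."""
    return ss.default_config(n_samples_per_group=4, n_replicates=3, seed=123)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return ss.generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_samples(small_cohort):
    return preprocess_records(small_cohort)


@pytest.fixture(scope="session")
def noiseless_config():
    """Deterministic signal: no noise, no sample or replicate variation."""
    return ss.default_config(noise_sd=0.0, sample_sd=0.0, replicate_sd=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
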