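import numpy as np
import pytest

from solqspr.synthetic import SyntheticSpec, generate_library, count_features


@pytest.fixture(scope="session")
def tight_library():
    """Small synthetic library in the low-noise measurement regime."""
    return generate_library(SyntheticSpec(n_molecules=120, seed=42, noise_sigma=0.17))


@pytest.fixture(scope="session")
def noiseless_library():
    return generate_library(SyntheticSpec(n_molecules=200, seed=7, noise_sigma=0.0))


@pytest.fixture(scope="session")
def records(tight_library):
    return list(tight_library.records)


@pytest.fixture(scope="session")
def counts(tight_library):
    return count_features(tight_library.records)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
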