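import numpy as np
import pytest

from chromspect.classify import train_fingerprint_model
from chromspect.synthetic import hidden_peak_scenario, make_library


@pytest.fixture(scope="session")
def trio():
    """Three-species hidden-peak scenario, fixed noise seed."""
    return hidden_peak_scenario(1, variant="three")


@pytest.fixture(scope="session")
def quint():
    """Five-species near-coelution scenario, fixed noise seed."""
    return hidden_peak_scenario(1, variant="five")


@pytest.fixture(scope="session")
def small_library():
    """8 species x 3 replicates at 1% noise."""
    return make_library(8, replicates_per_species=3, noise_sd=0.01, seed=0)


@pytest.fixture(scope="session")
def small_model(small_library):
    return train_fingerprint_model(small_library)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
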