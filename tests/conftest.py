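import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from adductscreen.chem import default_registry
from adductscreen.search import SearchConfig
from adductscreen.spectra import NoiseConfig


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def jb(registry):
    return registry["JB"]


@pytest.fixture(scope="session")
def cam(registry):
    return registry["carbamidomethyl"]


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def search_cfg():
    return SearchConfig()


@pytest.fixture
def noiseless():
    return NoiseConfig()
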