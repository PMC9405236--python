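import numpy as np
import pytest
from hypothesis import settings

from nlutadex.adex_core import preset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def tonic():
    return preset("Tonic spiking").params


@pytest.fixture(scope="session")
def delayed():
    return preset("Delayed accelerating").params


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
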