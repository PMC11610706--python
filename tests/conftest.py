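import numpy as np
import pytest

from g4screen.library import ReferenceTopology, enumerate_library
from g4screen.simulate import SimConfig


@pytest.fixture(scope="session")
def ref():
    return ReferenceTopology()


@pytest.fixture(scope="session")
def library(ref):
    """The full deduplicated 496-member library with rule classes."""
    return enumerate_library(ref)


@pytest.fixture()
def sim_cfg():
    return SimConfig()


@pytest.fixture()
def noiseless_cfg():
    return SimConfig(noise_sd=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
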