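import pytest

from homtandem.rules import structure_library
from homtandem.simulate import SimulationConfig


@pytest.fixture(scope="session")
def o8_library():
    return structure_library("limonene_o8")


@pytest.fixture(scope="session")
def o10_library():
    return structure_library("limonene_o10")


@pytest.fixture(scope="session")
def pool_library():
    return structure_library("limonene_pool")


@pytest.fixture(scope="session")
def pinene_library():
    return structure_library("alpha_pinene")


@pytest.fixture()
def noiseless_cfg():
    return SimulationConfig(mass_error_ppm_sd=0.0, seed=7)
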