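import numpy as np
import pytest

from faded.simulate import (
    GEUSAP_MODEL,
    SAPPHIRE_MODEL,
    SimulationConfig,
    make_decay,
    make_irf,
)


@pytest.fixture(scope="session")
def cuvette_config():
    """Default cuvette acquisition: 4096 channels / 20 ns, 42 ps IRF, 10^4 peak."""
    return SimulationConfig(seed=20260101)


@pytest.fixture(scope="session")
def irf(cuvette_config):
    return make_irf(cuvette_config)


@pytest.fixture(scope="session")
def sapphire_decay(cuvette_config, irf):
    return make_decay(SAPPHIRE_MODEL, irf, cuvette_config)


@pytest.fixture(scope="session")
def geusap_decay(irf):
    cfg = SimulationConfig(seed=20260102)
    return make_decay(GEUSAP_MODEL, irf, cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
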