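import numpy as np
import pytest

from emct2.dictionary import SimConfig, build_dictionary, make_grid
from emct2.sequence import MESEProtocol, build_mese_timeline


@pytest.fixture(scope="session")
def protocol():
    return MESEProtocol()


@pytest.fixture(scope="session")
def ideal_timeline(protocol):
    return build_mese_timeline(protocol, mode="ideal")


@pytest.fixture(scope="session")
def ideal_180_timeline():
    return build_mese_timeline(MESEProtocol(refocusing_flip_deg=180.0), mode="ideal")


@pytest.fixture(scope="session")
def small_dictionary(protocol):
    """Reduced ideal-pulse dictionary shared across matcher tests."""
    grid = make_grid(((10.0, 100.0, 5.0),), (0.7, 1.3, 0.05), 1500.0)
    return build_dictionary(grid, protocol, SimConfig(mode="ideal"))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
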