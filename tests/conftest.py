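import numpy as np
import pytest

from ribbonsyn.model import RibbonParams
from ribbonsyn.protocols import make_flash_protocol
from ribbonsyn.synth import ground_truth_calcium
from ribbonsyn.traces import Trace


@pytest.fixture(scope="session")
def params():
    """Prior-mode parameter set."""
    return RibbonParams(r_max=2.5, i_max=2.5, e_max=10.0, k=14.0, x0=0.5,
                        IP_max=13.8, RRP_max=4.0)


@pytest.fixture(scope="session")
def flash_protocol():
    return make_flash_protocol(n_flashes=3, dt=0.01)


@pytest.fixture(scope="session")
def flash_calcium(flash_protocol):
    stim, _ = flash_protocol
    return ground_truth_calcium(stim, tau_decay=0.3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def constant_calcium():
    def make(level: float, duration: float = 60.0, dt: float = 0.01):
        n = int(round(duration / dt)) + 1
        return Trace(np.full(n, level), dt=dt, kind="calcium")
    return make
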