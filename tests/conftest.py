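import numpy as np
import pytest

from rhythmboot.oscillator import extract_limit_cycle
from rhythmboot.simdata import SimulationConfig


@pytest.fixture
def times12():
    """The reference sampling design: 12 points, 4 h apart, 48 h span."""
    return np.arange(0.0, 48.0, 4.0)


@pytest.fixture(scope="session")
def goodwin_cycle():
    """One extracted limit cycle of the default oscillator (integration is
    the slow part, so share it across tests)."""
    return extract_limit_cycle()


@pytest.fixture
def small_config():
    def make(**kwargs):
        defaults = dict(n_rhythmic=20, n_null=20, n_individuals=12, seed=0)
        defaults.update(kwargs)
        return SimulationConfig(**defaults)

    return make
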