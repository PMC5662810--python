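import numpy as np
import pytest

from heartimm import synthetic
from heartimm.trace import RegimeSchedule


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def normal_trace():
    """40 s regular-rhythm motion trace at 100 Hz."""
    return synthetic.simulate_normal(40.0, 100.0, seed=7)


@pytest.fixture(scope="session")
def mixed_trace():
    """normal 30 s / AF 20 s / normal 30 s at 100 Hz."""
    schedule = RegimeSchedule([("normal", 30.0), ("af", 20.0), ("normal", 30.0)],
                              seed=11)
    return synthetic.simulate_mixed(schedule, 100.0)
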