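import numpy as np
import pytest

from pfimbalance import build_scenario


@pytest.fixture
def scenario1():
    """Moderate control risk (0.10), moderate treatment (RR 0.75), strong PF (RR 5)."""
    return build_scenario(1)


@pytest.fixture
def effects1(scenario1):
    return scenario1.effects


@pytest.fixture
def rng():
    return np.random.default_rng(20120522)
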