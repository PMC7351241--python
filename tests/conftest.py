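import numpy as np
import pytest

from stdpmux.stdp_rules import STDPRule
from stdpmux.synthetic_inputs import PopulationSpec


@pytest.fixture
def asym_rule():
    """Default asymmetric rule: tau_+ = 20 ms, tau_- = 50 ms."""
    return STDPRule("asymmetric", tau_plus=0.020, tau_minus=0.050, alpha=1.05,
                    mu=0.01, learning_rate=0.001)


@pytest.fixture
def sym_rule():
    return STDPRule("symmetric", tau_plus=0.020, tau_minus=0.050, alpha=1.05,
                    mu=0.01, learning_rate=0.001)


@pytest.fixture
def limit_cycle_specs():
    """Two symmetric populations at 5 and 9 Hz, sigma = 0.6 (multiplexing regime)."""
    return [
        PopulationSpec(size=120, freq_hz=5.0, gamma=1.0, intensity_mean=10.0, sigma=0.6),
        PopulationSpec(size=120, freq_hz=9.0, gamma=1.0, intensity_mean=10.0, sigma=0.6),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
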