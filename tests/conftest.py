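import numpy as np
import pytest

from pulsepd.io_cli import reference_population
from pulsepd.pulse_model import IndividualModel, PulseEvent


@pytest.fixture(scope="session")
def ref_pop():
    return reference_population()


@pytest.fixture()
def grid_24h():
    """Standard 24 h sampling grid at 10-min spacing (145 points)."""
    return np.linspace(0.0, 24.0, 145)


@pytest.fixture()
def typical_individual():
    """Typical subject: reference fixed effects, regular 1.57 h pulse train."""
    pulses = [PulseEvent(1.57 * i, 7.86, 0.182) for i in range(1, 16)]
    return IndividualModel(baseline=0.185, k_out=2.78, a0=1.05, pulses=pulses)


@pytest.fixture()
def rng():
    """Fresh, identically seeded generator per test (order-independent)."""
    return np.random.default_rng(20240917)
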