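import pytest

from biorefuq import EconConfig, calibrate_economics
from biorefuq.uncertainty import Measurement


@pytest.fixture(scope="session")
def calibrated_econ() -> EconConfig:
    """Economics calibrated so the default base case prices at $2.15/gal."""
    return calibrate_economics(target_mesp=2.15)


@pytest.fixture
def meas():
    """Shorthand Measurement factory."""

    def make(name, value, u, units=""):
        return Measurement(name, value, u, units)

    return make
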