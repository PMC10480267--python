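import numpy as np
import pytest

from alchemetric.systems import HarmonicAlchemy, ThermoParams


@pytest.fixture(scope="session")
def thermo():
    return ThermoParams()


@pytest.fixture(scope="session")
def harmonic():
    """The reference toy: k_A=1, k_B=4, exact dG = ln(4)/2."""
    return HarmonicAlchemy(k_A=1.0, k_B=4.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
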