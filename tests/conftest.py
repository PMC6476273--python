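import numpy as np
import pytest

from gpcrtune.doseresponse import FourPL
from gpcrtune.ternary import default_ternary_rates


@pytest.fixture(scope="session")
def base_ternary():
    """Tabulated base rates and totals of the ternary complex model."""
    return default_ternary_rates()


@pytest.fixture(scope="session")
def example_fourpl():
    """A representative activating 4PL: basal 100, max 10000, EC50 30 nM."""
    return FourPL(A=100.0, B=1.3, C=3e-8, D=1e4)


@pytest.fixture
def rng():
    return np.random.default_rng(1234567)
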