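import numpy as np
import pytest

from tvdmri.encoding import multishell_protocol, tensor_valued_protocol
from tvdmri.phantom import MicroDomain

TV_SHELL_B = np.array([100.0, 500.0, 900.0, 1200.0, 1600.0, 2000.0])


@pytest.fixture(scope="session")
def tv_protocol():
    return tensor_valued_protocol(seed=7)


@pytest.fixture(scope="session")
def ms_protocol():
    return multishell_protocol(seed=7)


@pytest.fixture(scope="session")
def zeppelin():
    """Default healthy white-matter microdomain."""
    return MicroDomain(1.7e-3, 0.2e-3, np.array([1.0, 0.0, 0.0]))


@pytest.fixture(scope="session")
def bvalues():
    return TV_SHELL_B.copy()
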