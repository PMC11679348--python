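import numpy as np
import pytest

from cpcdosy import AcquisitionParams

# acquisition used in the worked examples: gamma 2.675e8, delta 1.5 ms, Delta 0.1 s
EXAMPLE_ACQ = AcquisitionParams(gamma=2.675e8, little_delta=1.5e-3, big_delta=0.1)


@pytest.fixture
def acq() -> AcquisitionParams:
    return EXAMPLE_ACQ


@pytest.fixture
def ramp16() -> np.ndarray:
    return np.linspace(0.02, 0.5, 16)


@pytest.fixture
def ramp24() -> np.ndarray:
    return np.linspace(0.02, 0.6, 24)
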