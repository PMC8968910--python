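import numpy as np
import pytest

from magnegel.magnetics import calibrate_device, default_device


@pytest.fixture(scope="session")
def device():
    """Uncalibrated default two-magnet device."""
    return default_device()


@pytest.fixture(scope="session")
def calibrated_device(device):
    """Device calibrated to the 52.3 mT midpoint target."""
    return calibrate_device(device, 52.3e-3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
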