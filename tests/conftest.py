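import numpy as np
import pytest

from cdmspipe.instrument import AcquisitionConfig, TrapCalibration


@pytest.fixture(scope="session")
def cal():
    return TrapCalibration()


@pytest.fixture(scope="session")
def cal0():
    """Noiseless calibration."""
    return TrapCalibration(noise_rms=0.0)


@pytest.fixture(scope="session")
def acq():
    """Full 500 ms acquisition."""
    return AcquisitionConfig()


@pytest.fixture(scope="session")
def acq200():
    """Shortened 200 ms trap for fast tests."""
    return AcquisitionConfig(trap_ms=200.0)


@pytest.fixture(scope="session")
def acq100():
    """Shortened 100 ms trap for fast tests."""
    return AcquisitionConfig(trap_ms=100.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
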