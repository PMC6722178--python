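import numpy as np
import pytest

from swaysim import ControllerParams, DeviceConfig, SubjectProfile
from swaysim.simulator import device_stiffness


@pytest.fixture
def profile() -> SubjectProfile:
    return SubjectProfile("s001", "control", mass=72.0, height=1.70,
                          com_height=0.935)


@pytest.fixture
def device() -> DeviceConfig:
    return DeviceConfig()


@pytest.fixture
def stable_controller(profile, device) -> ControllerParams:
    """A comfortably stable delayed PD controller for the device plant."""
    s_eff = device_stiffness(profile, device)
    inertia = s_eff * device.pendulum_com_height / 9.81
    k = 1.3 * s_eff
    b = 2 * 1.2 * np.sqrt((k - s_eff) * inertia)
    return ControllerParams(k, b, delay=0.15, noise_gain=2.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
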