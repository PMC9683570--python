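import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from cavclamp.protocol import build_step_step_ramp
from cavclamp.simcell import ca_cell

NO_RUNDOWN = (0.0, 50.0, 0.0, 400.0, 1.0)


@pytest.fixture(scope="session")
def ssr_protocol():
    """The standard step-step-ramp protocol (10 kHz, 0.2 Hz, LJP 17 mV)."""
    return build_step_step_ramp()


@pytest.fixture(scope="session")
def quiet_cell():
    """Noise-free default Ca2+ cell with rundown disabled."""
    return ca_cell(noise_sd=0.0, rundown=NO_RUNDOWN)


@pytest.fixture(scope="session")
def leak_cell():
    """Leak-only cell (no channels, ideal clamp) with modest noise."""
    return ca_cell(g_max=0.0, r_s=0.0, noise_sd=2.0, rundown=NO_RUNDOWN)
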