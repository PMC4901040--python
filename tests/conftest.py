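import pytest
from hypothesis import HealthCheck, settings

from cagetrack import (
    BaseplateGeometry,
    LightSchedule,
    constant_profile,
    simulate_cage,
)

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def geometry():
    return BaseplateGeometry()


@pytest.fixture(scope="session")
def schedule():
    return LightSchedule()


@pytest.fixture(scope="session")
def small_cage():
    """A 10-minute cage of three busy animals with ground truth and reads."""
    profile = constant_profile(0.9)
    truth, reads = simulate_cage(profile, duration_s=600.0, seed=7)
    return truth, reads
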