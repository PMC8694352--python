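import pytest
from hypothesis import HealthCheck, settings

import bubbleflux as bf

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def tea():
    """The shipped 1 M aqueous TEA system at 30 °C (air-saturated, CO2-free)."""
    return bf.default_system()


@pytest.fixture(scope="session")
def tea_medium(tea):
    return tea.medium


@pytest.fixture(scope="session")
def tea_column(tea):
    return tea.column
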