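import pytest
from hypothesis import HealthCheck, settings

from ppdkrp import Environment, RateParameters

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def params() -> RateParameters:
    """Normalized default rate constants (avid binding, Vk/Vp0 = 1/2)."""
    return RateParameters()


@pytest.fixture
def env() -> Environment:
    """Mid-range light input, PPDK_T/RP_T = 100, saturating substrates."""
    return Environment()
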