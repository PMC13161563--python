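import pytest
from hypothesis import HealthCheck, settings

from cagmir.guides import A2, RepeatTarget, design_variants

settings.register_profile(
    "derandomized",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("derandomized")


@pytest.fixture(scope="session")
def variants():
    return design_variants()


@pytest.fixture(scope="session")
def cag28():
    return RepeatTarget("CAG", 28)


@pytest.fixture(scope="session")
def a2():
    return A2
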