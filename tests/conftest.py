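import pytest
from hypothesis import HealthCheck, settings

from adtcea.synthetic import gen_fixture

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fixture_params():
    """The full default parameter fixture (printed + synthetic values)."""
    return gen_fixture(seed=0)


@pytest.fixture(scope="session")
def fast_params(fixture_params):
    """Fixture with a 5-year horizon: same model, 65 cycles, for speed."""
    return fixture_params.with_edits({"settings.horizon_years": 5.0})
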