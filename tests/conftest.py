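import pytest
from hypothesis import HealthCheck, settings

from pscea import IpdSimSpec, simulate_ipd, base_case_fixture

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture
def fixture_config():
    """The packaged three-arm configuration (fresh copy per test)."""
    return base_case_fixture()


WEIBULL_TRUTH = {"shape": 1.3, "scale": 10.0}


@pytest.fixture(scope="session")
def censored_weibull_ipd():
    """5,000 Weibull subjects with ~20% uniform censoring, fixed seed."""
    return simulate_ipd(
        IpdSimSpec(
            n=5000,
            family="weibull",
            params=(WEIBULL_TRUTH["shape"], WEIBULL_TRUTH["scale"]),
            random_censor_frac=0.2,
            seed=42,
        )
    )
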