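import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import glucofilt as gf

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def normal_params():
    return gf.ModelParameters.normal()


@pytest.fixture(scope="session")
def t2dm_params():
    return gf.ModelParameters.t2dm()


@pytest.fixture(scope="session", params=["normal", "t2dm"])
def cohort_params(request):
    return gf.ModelParameters.from_profile(request.param)


@pytest.fixture(scope="session")
def meal_schedule():
    return gf.standard_meal_schedule()


@pytest.fixture(scope="session")
def no_meal():
    return gf.MealSchedule(())


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_psd(rng: np.random.Generator, n: int, scale: float = 1.0) -> np.ndarray:
    """Well-conditioned random PSD matrix for point-set property tests."""
    a = rng.standard_normal((n, n))
    return scale * (a @ a.T + n * np.eye(n))
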