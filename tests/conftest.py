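import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from affecthr.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Three short sessions, enough to exercise every downstream stage."""
    config = CohortConfig(n_subjects=3, duration_range_s=(240, 300), seed=11)
    return generate_cohort(config), config


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
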