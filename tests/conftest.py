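import pytest
from hypothesis import HealthCheck, settings

import ogttbcf as o

settings.register_profile(
    "suite", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture()
def fixture_cohort() -> o.Cohort:
    return o.worked_fixture()


@pytest.fixture(scope="session")
def small_cohort() -> o.Cohort:
    """Default-size synthetic cohort with follow-up, shared across tests."""
    return o.generate_cohort(o.CohortConfig(seed=7), seed=7)


@pytest.fixture(scope="session")
def small_matrix(small_cohort) -> o.IndexMatrix:
    return o.compute_index_matrix(small_cohort)
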