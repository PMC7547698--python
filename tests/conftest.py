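import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mifmodel.estimation import (
    DEFAULT_RANGES,
    SearchConfig,
    cohort_variances,
)
from mifmodel.model_core import predict_performance
from mifmodel.recovery import draw_generating_parameters

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ranges():
    return dict(DEFAULT_RANGES)


@pytest.fixture(scope="session")
def fast_config():
    """Reduced-budget search for unit tests that only need convergence
    to a loose tolerance."""
    return SearchConfig(n_samples=8000, top_k=200, seed=7)


@pytest.fixture(scope="session")
def small_cohort(ranges):
    """Ten noise-free synthetic subjects with their PM variances."""
    params = draw_generating_parameters(10, ranges, seed=42)
    pms = [predict_performance(p) for p in params]
    return params, pms, cohort_variances(pms)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
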