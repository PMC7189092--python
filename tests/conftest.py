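import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cqrsurv as cs

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return cs.StandardizationParams(mean_age=47.04, sd_age=10.70)


@pytest.fixture(scope="session")
def small_synthetic():
    """One modest synthetic cohort shared by read-only tests."""
    return cs.generate_cohort(cs.CohortConfig(n=300, seed=17))


@pytest.fixture(scope="session")
def default_cohort_5000():
    """The calibrated default cohort at the size the calibration checks use."""
    return cs.generate_cohort(cs.CohortConfig(n=5000, seed=20160118))


def random_survival_sample(rng, n, tie_prob=0.3):
    """Small random censored sample with ties, for oracle comparisons."""
    t = rng.exponential(10.0, n)
    if tie_prob:
        # force ties by rounding a subset to one decimal
        m = rng.random(n) < tie_prob
        t[m] = np.round(t[m], 0) + 0.5
    t = np.maximum(t, 0.1)
    d = (rng.random(n) < 0.6).astype(int)
    return t, d
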