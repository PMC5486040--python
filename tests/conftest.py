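import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import torusom as t

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Small full-separation cohort for fast unit tests."""
    cfg = t.ScenarioConfig(n_patients=30, n_controls=60, n_markers=4,
                           scenario="full_separation", seed=11)
    return t.generate_cohort(cfg)


@pytest.fixture(scope="session")
def full_cohort():
    """Study-sized full-separation cohort (102 patients, 301 controls, d=10)."""
    return t.generate_cohort(t.ScenarioConfig(scenario="full_separation", seed=7))


@pytest.fixture(scope="session")
def preprocessed_full(full_cohort):
    pre, _ = t.preprocess_cohort(full_cohort)
    return pre


@pytest.fixture(scope="session")
def trained_small(small_cohort):
    """A small trained map shared across height/cluster tests."""
    pre, _ = t.preprocess_cohort(small_cohort)
    som = t.ToroidalESOM(rows=10, cols=16, epochs=10, radius_start=4.0,
                         random_state=3).fit(pre.values)
    return som, pre
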