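import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tonechange as tc

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def exp1_config():
    return tc.load_preset("exp1")


@pytest.fixture(scope="session")
def exp3_config():
    return tc.load_preset("exp3")


@pytest.fixture(scope="session")
def exp4_config():
    return tc.load_preset("exp4")


@pytest.fixture(scope="session")
def exp1_trials(exp1_config):
    return tc.generate_trial_set(exp1_config, seed=7)


@pytest.fixture(scope="session")
def exp4_trials(exp4_config):
    return tc.generate_trial_set(exp4_config, seed=7)


@pytest.fixture(scope="session")
def small_cohort(exp1_trials):
    """12 Bayesian-regime subjects on the fixed exp1 trial set."""
    return tc.simulate_cohort(exp1_trials, tc.REGIMES["bayesian"], 12, seed=11)


@pytest.fixture(scope="session")
def small_summaries(exp1_trials, small_cohort):
    return tc.condition_summaries(small_cohort, exp1_trials)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_sequence(values, condition=None, config=None):
    """Bare StimulusSequence for unit tests on metrics/observer."""
    values = np.asarray(values, dtype=float)
    if condition is None:
        condition = tc.Condition(
            precision_level="high", precision_value=64.0,
            mean_change_level="high", mean_change_value=1.0, direction="up",
        )
    return tc.StimulusSequence(
        condition=condition, exemplar_index=1, values=values,
        pre_change_mean=0.0, onsets=np.arange(values.size, dtype=float),
        trial_id="test-01",
    )
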