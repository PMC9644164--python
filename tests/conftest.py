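import numpy as np
import pytest

from esngait.preprocess import PreprocessConfig
from esngait.protocols import prepare_trial
from esngait.synthetic_gait import (
    SyntheticTrialSpec,
    running_pattern,
    synthesize_cohort,
    synthesize_trial,
    walking_pattern,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def walking_trial():
    """One clean walking trial (10 strides, seeded)."""
    return synthesize_trial(
        SyntheticTrialSpec(pattern=walking_pattern(), n_strides=10, seed=11)
    )


@pytest.fixture(scope="session")
def running_trial():
    return synthesize_trial(
        SyntheticTrialSpec(pattern=running_pattern(), n_strides=10, seed=12)
    )


@pytest.fixture(scope="session")
def mini_cohort():
    """2 walking + 2 running trials, 14 strides each (for protocol tests)."""
    return synthesize_cohort(
        2,
        SyntheticTrialSpec(pattern=walking_pattern(), n_strides=14),
        SyntheticTrialSpec(pattern=running_pattern(), n_strides=14),
        master_seed=99,
    )


@pytest.fixture(scope="session")
def mini_prepared(mini_cohort):
    cfg = PreprocessConfig(detrend_integrals=True)
    return [prepare_trial(t, cfg) for t in mini_cohort]
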