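import numpy as np
import pytest

from moodcue import StudyDesign, schedule_study, simulate_cohort
from moodcue.cohort import GroupParams


@pytest.fixture(scope="session")
def design():
    return StudyDesign()


@pytest.fixture(scope="session")
def schedule(design):
    return schedule_study(design, seed=1)


@pytest.fixture(scope="session")
def group_high():
    return GroupParams.high_mdq()


@pytest.fixture(scope="session")
def group_low():
    return GroupParams.low_mdq()


@pytest.fixture(scope="session")
def small_cohort(design):
    """A small default-parameter cohort shared by integration-level tests."""
    return simulate_cohort(design, GroupParams.high_mdq(), GroupParams.low_mdq(),
                           n_per_group=5, seed=11)


def quiet_params(label="test", **overrides):
    """GroupParams with all noise and contamination switched off."""
    base = dict(label=label, mood_mean_neg=7.0, mood_mean_pos=12.0,
                delta_neg=0.0, delta_pos=0.0, rt_noise_sigma=0.0,
                error_rate=0.0, outlier_rate=0.0, oob_rate=0.0,
                unrecorded_rate=0.0, compliance=1.0)
    base.update(overrides)
    return GroupParams(**base)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
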