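import numpy as np
import pytest

from pupilclust.schedule import build_schedule
from pupilclust.synthetic import generate_cohort, NoiseConfig


@pytest.fixture(scope="session")
def schedule():
    return build_schedule()


@pytest.fixture(scope="session")
def tiny_schedule():
    # 2 blocks x 2 levels x 3 trials, one deceptive cell
    return build_schedule(2, 2, 3, {(2, 1)})


@pytest.fixture(scope="session")
def pupil_cohort(schedule):
    """Default-size cohort, pupil/behavior channels only (fast)."""
    return generate_cohort(schedule=schedule, seed=7, channels=("pupil",))


@pytest.fixture(scope="session")
def small_multimodal_cohort(schedule):
    """12-participant cohort with every channel, for integration tests."""
    return generate_cohort(schedule=schedule, n_per_archetype=(6, 6), seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
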