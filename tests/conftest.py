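import numpy as np
import pytest

from knowrare.config import SynthConfig, TaskSpec
from knowrare.preprocess import preprocess_cohort
from knowrare.synthetic import generate_cohort


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    """A small but structured cohort: 20 conditions in 4 planted clusters."""
    return SynthConfig(n_patients=600, cluster_similarity_strength=0.9, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_preprocessed(small_cohort, small_config):
    return preprocess_cohort(small_cohort, small_config.task,
                             small_config.n_variables, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def icu_task() -> TaskSpec:
    return TaskSpec.named("icu_mortality")
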