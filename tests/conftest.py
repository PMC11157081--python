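import numpy as np
import pytest

from hypojump import pipeline, synth
from hypojump.config import CohortConfig


@pytest.fixture(scope="session")
def zero_noise_config() -> CohortConfig:
    return CohortConfig(emg_noise_sd=0.0, grf_noise_sd=0.0, marker_noise_sd=0.0)


@pytest.fixture(scope="session")
def participant(zero_noise_config):
    return synth.draw_participants(zero_noise_config)[0]


@pytest.fixture(scope="session")
def zero_noise_trial(participant, zero_noise_config):
    return synth.generate_trial(participant, "PRE", 123, zero_noise_config)


@pytest.fixture(scope="session")
def norm_peaks(participant, zero_noise_config):
    maxjs = [
        synth.generate_trial(
            participant, "PRE", synth.trial_seed(0, 0, "MAX", j), zero_noise_config, j,
            max_jump=True,
        )[0]
        for j in range(3)
    ]
    return pipeline.normalization_peaks(maxjs)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
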