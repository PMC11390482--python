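import numpy as np
import pytest

from oddball2p.config import GeneratorConfig, SessionConfig
from oddball2p.synthetic import generate_session


@pytest.fixture(scope="session")
def small_session():
    """A compact but complete session: 2 animals x 10 cells, 60+16 trials."""
    cfg = SessionConfig(
        n_trials_block1=80,
        n_trials_block2=20,
        n_animals=2,
        cells_per_animal=10,
        seed=11,
    )
    trials, events, truth, behavior, traces = generate_session(cfg)
    return cfg, trials, events, truth, behavior, traces


@pytest.fixture(scope="session")
def noiseless_generator():
    """Generator settings with every stochastic nuisance switched off."""
    return GeneratorConfig(
        noise_sd=0.0,
        amplitude_jitter=0.0,
        running_gain_sd=0.0,
        animal_effect_sd=0.0,
        oddball_deceleration=0.0,
        pupil_outlier_fraction=0.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
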