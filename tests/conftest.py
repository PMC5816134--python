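import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import vocalrep.synthdata as sd

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_world():
    """A compact 4-type world small enough for fast downstream fits."""
    return sd.make_world(n_stimuli=40, n_types=4, dim=2,
                         compact_types=("laugh", "cry"), spread=0.8,
                         separation=5.0, seed=11)


@pytest.fixture(scope="session")
def default_world():
    """The documented default study scale: 132 stimuli, 6 types, 2 compact."""
    return sd.make_world(seed=7)


@pytest.fixture(scope="session")
def english_lexicon(default_world):
    return sd.default_lexicon(default_world, "english", seed=7)


@pytest.fixture(scope="session")
def naming_trials(default_world, english_lexicon):
    return sd.simulate_naming(default_world, english_lexicon, 20,
                              sd.GenParams(), seed=21)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
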