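import numpy as np
import pytest
from hypothesis import settings

from mseienet import EEGTrialSet, SyntheticConfig, generate_mi_trials

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_trials(rng) -> EEGTrialSet:
    """10 trials, 3 channels, 1000 samples, 4 balanced-ish classes."""
    data = rng.standard_normal((10, 3, 1000))
    labels = np.array([0, 1, 2, 3, 0, 1, 2, 3, 0, 1])
    return EEGTrialSet(
        data=data, labels=labels, fs=250.0,
        channel_names=("C3", "Cz", "C4"),
        class_names=("L", "R", "F", "T"),
    )


@pytest.fixture(scope="session")
def synthetic_small() -> EEGTrialSet:
    """Short synthetic set shared across tests (1 s trials, 5 per class)."""
    cfg = SyntheticConfig(n_trials_per_class=5, duration=1.0, seed=7)
    return generate_mi_trials(cfg)
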