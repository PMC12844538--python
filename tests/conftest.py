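import numpy as np
import pytest

from emofuse import FusionModelConfig, SyntheticConfig, generate_dataset
from emofuse.train import prepare_inputs


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_synth_config():
    """Desk-scale dataset: short trials, few subjects, low audio rate."""
    return SyntheticConfig(
        n_subjects=2, n_trials=6, trial_seconds=8.0, audio_rate=4000, seed=7
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_synth_config):
    return generate_dataset(tiny_synth_config)


@pytest.fixture(scope="session")
def tiny_model_config():
    return FusionModelConfig(audio_branch_rate=250.0)


@pytest.fixture(scope="session")
def tiny_arrays(tiny_dataset, tiny_model_config):
    """Prepared model inputs for the tiny dataset (12 trials)."""
    return prepare_inputs(tiny_dataset, tiny_model_config)
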