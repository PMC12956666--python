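import numpy as np
import pytest

from eegmdh.features import extract_features
from eegmdh.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config():
    """A cheap dataset: 6 subjects × 8 tasks, 4 channels, 2 s epochs."""
    return GeneratorConfig(n_subjects=6, n_channels=4, duration=2.0, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_features(small_dataset):
    X = np.vstack([extract_features(t) for t in small_dataset.trials])
    return X, small_dataset.encoded_labels()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
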