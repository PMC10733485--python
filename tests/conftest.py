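import numpy as np
import pytest

from mdfjo.config import Config
from mdfjo.io import EpochedTrials
from mdfjo.synth import SyntheticSpec, checkerboard_case, generate


@pytest.fixture(scope="session")
def checkerboard():
    return checkerboard_case()


@pytest.fixture(scope="session")
def default_synth():
    """One default-condition synthetic dataset (100 trials/class, 20 ch)."""
    return generate(SyntheticSpec(seed=0))


@pytest.fixture(scope="session")
def small_synth():
    """A light dataset for pipeline-level tests: 30 trials/class, 10 channels."""
    spec = SyntheticSpec(n_per_class=30, n_channels=10, active_channels=(3, 7), seed=7)
    return generate(spec)


@pytest.fixture(scope="session")
def small_config():
    """Config sized for the small dataset: 2 channel modes, coarse lambda grid."""
    return Config(mode_sizes=(5, "all"), lam_grid=(0.0, 0.3, 0.6, 0.9), inner_folds=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_trials(rng, n_trials=12, n_channels=4, n_samples=200, fs=100.0):
    data = rng.standard_normal((n_trials, n_channels, n_samples))
    labels = (np.arange(n_trials) % 2) + 1
    names = tuple(f"CH{i}" for i in range(n_channels))
    return EpochedTrials(data=data, labels=labels, fs=fs, channel_names=names)
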