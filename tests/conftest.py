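import numpy as np
import pytest

from frfteeg import ClassLabel, SynthConfig, generate_trial


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_synth_cfg():
    """A fast generator configuration for unit tests."""
    return SynthConfig(n_trials_per_class=4, epoch_len=256, seed=7)


@pytest.fixture
def clean_epoch(small_synth_cfg):
    return generate_trial(small_synth_cfg, ClassLabel.NORMAL)


@pytest.fixture
def planted_matrix():
    """240x34 matrix with 5 informative features (1.5 SD class shift)."""

    def make(seed: int):
        r = np.random.default_rng(seed)
        y = np.repeat([0, 1], 120)
        r.shuffle(y)
        X = r.normal(size=(240, 34))
        planted = r.choice(34, size=5, replace=False)
        X[:, planted] += 1.5 * y[:, None]
        return X, y, set(int(i) for i in planted)

    return make
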