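import numpy as np
import pytest

from colearn.model import EnvironmentConfig, LearningConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def env():
    """A representative environment where the high cue is more reliable but
    the low cue benefits from independent observations."""
    return EnvironmentConfig(r_low=0.7, r_high=0.8)


@pytest.fixture
def quick_learning():
    """Scaled-down training protocol for fast unit tests."""
    return LearningConfig(n_reps=30, n_trials=300, window=50)


def mc_collective_accuracy(p, n, env, n_trials, rng):
    """Monte-Carlo oracle: empirical accuracy of simple-majority groups of n
    fixed-behavior voters over n_trials independent decision trials.

    Independent of the analytic route: simulates raw signals and votes.
    """
    superior = rng.integers(2, size=(n_trials, 1))
    high = np.where(rng.random((n_trials, 1)) < env.r_high, superior, 1 - superior)
    low = np.where(rng.random((n_trials, n)) < env.r_low, superior, 1 - superior)
    conflict = low != high
    follow_low = rng.random((n_trials, n)) < p
    votes = np.where(conflict & ~follow_low, high, low)
    votes_A = n - votes.sum(axis=1)
    coin = rng.integers(2, size=n_trials)
    chosen = np.where(2 * votes_A > n, 0, np.where(2 * votes_A < n, 1, coin))
    return float((chosen == superior[:, 0]).mean())
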