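import numpy as np
import pytest

from robustcsp import SyntheticConfig, TrialDataset


def brute_force_l1_optimum(Y: np.ndarray) -> float:
    """Exact max of ||w'Y||_1 over unit w by sign enumeration.

    For any fixed sign vector s the inner maximum over unit w of w'(Y s) is
    ||Y s||_2, so the global optimum is the best of the 2^q sign patterns.
    """
    d, q = Y.shape
    assert q <= 12, "enumeration oracle limited to small column counts"
    best = 0.0
    for bits in range(2 ** q):
        s = np.array([1.0 if bits >> j & 1 else -1.0 for j in range(q)])
        best = max(best, float(np.linalg.norm(Y @ s)))
    return best


def random_spd(rng, dim: int, n_vectors: int = None) -> np.ndarray:
    n_vectors = n_vectors or 2 * dim
    A = rng.normal(size=(dim, n_vectors))
    return A @ A.T / n_vectors


def make_dataset(rng, n_trials=12, n_channels=3, n_samples=50, fs=100.0,
                 role="train") -> TrialDataset:
    """Small random dataset with alternating labels."""
    trials = [rng.normal(size=(n_channels, n_samples)) for _ in range(n_trials)]
    labels = np.array([1 if i % 2 == 0 else 2 for i in range(n_trials)])
    return TrialDataset(trials=trials, labels=labels, sampling_rate=fs, role=role)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_config():
    """An 8-channel, quick-to-simulate recording with a clear class contrast."""
    return SyntheticConfig(n_channels=8, n_trials_per_class=20,
                           class_variance_ratio=8.0, snr=10.0,
                           n_background_sources=4, mixing_seed=3, noise_seed=4)
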