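"""Shared containers for epoched EEG trials, class covariances and spatial filters.

Conventions used throughout the package:

* a *trial* is a ``(n_channels, n_samples)`` real array in microvolts;
* class labels are the integers 1 and 2 (e.g. left- vs right-hand motor imagery);
* spatial filters are column vectors: applying a filter set ``W`` to a trial
  ``X`` yields the surrogate channels ``W.T @ X``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VALID_METHODS = ("csp_l2", "csp_tr", "csp_l1svd")


@dataclass
class TrialDataset:
    """A labelled collection of same-shape EEG trials.

    Parameters
    ----------
    trials
        List of ``(n_channels, n_samples)`` arrays. All trials must share both
        dimensions and contain only finite values.
    labels
        Per-trial class, each 1 or 2.
    sampling_rate
        Sampling frequency in Hz.
    channel_names
        Ordered channel identifiers; generated if omitted.
    role
        ``"train"`` or ``"test"``.
    """

    trials: list
    labels: np.ndarray
    sampling_rate: float
    channel_names: list = None
    role: str = "train"

    def __post_init__(self):
        self.trials = [np.asarray(t, dtype=float) for t in self.trials]
        self.labels = np.asarray(self.labels, dtype=int)
        if self.channel_names is None and self.trials:
            self.channel_names = [f"ch{i + 1:02d}" for i in range(self.trials[0].shape[0])]
        self.validate()

    def validate(self):
        if len(self.trials) != len(self.labels):
            raise ValueError("shape mismatch: trial count != label count")
        if self.role not in ("train", "test"):
            raise ValueError(f"invalid parameter: role {self.role!r}")
        shapes = {t.shape for t in self.trials}
        if len(shapes) > 1:
            raise ValueError(f"shape mismatch: trials have inconsistent shapes {shapes}")
        for t in self.trials:
            if t.ndim != 2:
                raise ValueError("shape mismatch: trials must be 2-D channel x sample arrays")
            if not np.all(np.isfinite(t)):
                raise ValueError("invalid data: non-finite values in trial")
        bad = set(np.unique(self.labels)) - {1, 2}
        if bad:
            raise ValueError(f"invalid data: labels must be 1 or 2, got {sorted(bad)}")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_channels(self) -> int:
        return self.trials[0].shape[0] if self.trials else 0

    @property
    def n_samples(self) -> int:
        return self.trials[0].shape[1] if self.trials else 0

    def class_indices(self, class_id: int) -> np.ndarray:
        return np.flatnonzero(self.labels == class_id)

    def copy(self) -> "TrialDataset":
        return TrialDataset(
            trials=[t.copy() for t in self.trials],
            labels=self.labels.copy(),
            sampling_rate=self.sampling_rate,
            channel_names=list(self.channel_names) if self.channel_names else None,
            role=self.role,
        )

    def subset(self, indices, role=None) -> "TrialDataset":
        indices = np.asarray(indices, dtype=int)
        return TrialDataset(
            trials=[self.trials[i] for i in indices],
            labels=self.labels[indices],
            sampling_rate=self.sampling_rate,
            channel_names=list(self.channel_names) if self.channel_names else None,
            role=role or self.role,
        )


@dataclass
class CovarianceMatrix:
    """A symmetric PSD channel-by-channel covariance, optionally trace-normalized."""

    matrix: np.ndarray
    n_trials_pooled: int
    normalized: bool

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.validate()

    def validate(self):
        C = self.matrix
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError("shape mismatch: covariance must be square")
        scale = max(np.abs(C).max(), 1e-300)
        if np.abs(C - C.T).max() > 1e-10 * scale:
            raise ValueError("invalid data: covariance not symmetric")
        evals = np.linalg.eigvalsh(0.5 * (C + C.T))
        if evals.min() < -1e-10 * max(evals.max(), 0.0):
            raise ValueError("invalid data: covariance not positive semi-definite")
        if self.normalized and abs(np.trace(C) - 1.0) > 1e-10:
            raise ValueError("invalid data: normalized covariance must have unit trace")

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]


@dataclass
class EigenProblem:
    """Result of decomposing the CSP target ``Y = C2^{-1} C1``.

    ``W`` holds the extracted directions as columns; ``V = W.T @ Y``; ``scores``
    are generalized eigenvalues for the L2/Tikhonov routes and per-direction L1
    dispersions ``||w.T Y||_1`` for the L1 route.
    """

    Y: np.ndarray
    W: np.ndarray
    V: np.ndarray
    scores: np.ndarray


@dataclass
class SpatialFilterSet:
    """An ordered bank of ``2 * n_pairs`` spatial filters.

    The first ``n_pairs`` columns maximize class-1 variance, the remaining
    ``n_pairs`` maximize class-2 variance.
    """

    filters: np.ndarray
    scores: np.ndarray
    method: str
    alpha: float = None
    channel_names: list = None

    def __post_init__(self):
        self.filters = np.asarray(self.filters, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        self.validate()

    def validate(self):
        if self.method not in VALID_METHODS:
            raise ValueError(f"invalid method: {self.method!r}")
        if self.filters.ndim != 2:
            raise ValueError("shape mismatch: filters must be a 2-D matrix")
        if self.filters.shape[1] % 2 != 0:
            raise ValueError("shape mismatch: filter count must be 2 * n_pairs")
        if not np.all(np.isfinite(self.filters)):
            raise ValueError("invalid data: non-finite filter coefficients")
        norms = np.linalg.norm(self.filters, axis=0)
        if np.any(norms == 0):
            raise ValueError("invalid data: zero filter column")

    @property
    def n_pairs(self) -> int:
        return self.filters.shape[1] // 2

    @property
    def n_channels(self) -> int:
        return self.filters.shape[0]


@dataclass
class FeatureVector:
    """Log-variance features of one trial's surrogate channels."""

    values: np.ndarray
    trial_id: int = None
    label: int = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("invalid data: non-finite feature values")


def canonicalize_sign(w: np.ndarray) -> np.ndarray:
    """Flip ``w`` so its largest-magnitude entry is positive (reproducible signs)."""
    w = np.asarray(w, dtype=float)
    idx = int(np.argmax(np.abs(w)))
    if w[idx] < 0:
        return -w
    return w


def canonicalize_columns(W: np.ndarray) -> np.ndarray:
    W = np.array(W, dtype=float, copy=True)
    for j in range(W.shape[1]):
        W[:, j] = canonicalize_sign(W[:, j])
    return W


def derive_seed(*parts) -> int:
    """Mix integer parts into a sub-seed below 2**31 (splitmix64-style).

    Used to give every (rate, repetition, purpose) combination an independent,
    reproducible random stream derived from one master seed.
    """
    mask = (1 << 64) - 1
    x = 0x9E3779B97F4A7C15
    for p in parts:
        x = (x + int(p) + 0x9E3779B97F4A7C15) & mask
        z = x
        z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & mask
        z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & mask
        z = z ^ (z >> 31)
        x = z
    return int(x % (1 << 31))
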