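"""Band-pass filtering, epoch windowing, filter application and log-variance features."""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .types import FeatureVector, SpatialFilterSet

#: Standard mu+beta motor-imagery band (Hz).
DEFAULT_BAND = (8.0, 30.0)
#: Post-cue analysis window (seconds from trial onset).
DEFAULT_WINDOW = (0.5, 2.5)
FILTER_ORDER = 5


def bandpass_epoch(trial, sampling_rate: float, band=DEFAULT_BAND,
                   window=DEFAULT_WINDOW):
    """Zero-phase Butterworth band-pass, then crop to the analysis window.

    The filter is applied forward-backward (``sosfiltfilt``) so the epoch is not
    phase-shifted. The returned epoch has ``round((end - start) * rate)``
    samples starting at ``round(start * rate)``.
    """
    X = np.asarray(trial, dtype=float)
    if X.ndim != 2:
        raise ValueError("shape mismatch: trial must be channel x sample")
    low, high = float(band[0]), float(band[1])
    nyq = sampling_rate / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"invalid band: need 0 < low < high < {nyq} Hz, got {band}")
    start, end = float(window[0]), float(window[1])
    i0 = int(round(start * sampling_rate))
    n_out = int(round((end - start) * sampling_rate))
    if start < 0 or n_out < 1 or i0 + n_out > X.shape[1]:
        raise ValueError(f"window out of range: {window} s in a "
                         f"{X.shape[1] / sampling_rate:g} s trial")
    sos = butter(FILTER_ORDER, [low, high], btype="bandpass", fs=sampling_rate,
                 output="sos")
    filtered = sosfiltfilt(sos, X, axis=1)
    return filtered[:, i0:i0 + n_out]


def apply_filters(filters, trial) -> np.ndarray:
    """Project a trial onto spatial filters: surrogate channels ``W.T @ X``."""
    W = filters.filters if isinstance(filters, SpatialFilterSet) else np.asarray(filters, float)
    X = np.asarray(trial, dtype=float)
    if X.ndim != 2 or W.ndim != 2:
        raise ValueError("shape mismatch: expected 2-D arrays")
    if W.shape[0] != X.shape[0]:
        raise ValueError(f"shape mismatch: {W.shape[0]} filter rows vs "
                         f"{X.shape[0]} trial channels")
    return W.T @ X


def log_variance_features(surrogate, normalize: bool = False, trial_id=None,
                          label=None) -> FeatureVector:
    """Log of each surrogate channel's sample variance (ddof=1).

    With ``normalize`` the variances are first divided by their sum, the
    classical CSP band-power normalization; without it the features carry the
    absolute power scale (and shift by ``2 log a`` under amplitude scaling
    ``a``).
    """
    Z = np.asarray(surrogate, dtype=float)
    if Z.ndim != 2:
        raise ValueError("shape mismatch: surrogate must be 2-D")
    if Z.shape[1] < 2:
        raise ValueError("invalid data: need >= 2 samples per surrogate channel")
    var = Z.var(axis=1, ddof=1)
    if np.any(var == 0):
        raise ValueError("degenerate surrogate: zero-variance surrogate channel")
    if normalize:
        values = np.log(var / var.sum())
    else:
        values = np.log(var)
    return FeatureVector(values=values, trial_id=trial_id, label=label)


def feature_matrix(trials, filters, normalize: bool = False) -> np.ndarray:
    """Stack log-variance feature vectors for a list of trials into an array."""
    rows = [log_variance_features(apply_filters(filters, t), normalize=normalize).values
            for t in trials]
    return np.vstack(rows)


def preprocess_dataset(dataset, band=DEFAULT_BAND, window=DEFAULT_WINDOW):
    """Band-pass and window every trial of a dataset; returns a new dataset."""
    from .types import TrialDataset

    trials = [bandpass_epoch(t, dataset.sampling_rate, band, window)
              for t in dataset.trials]
    return TrialDataset(trials=trials, labels=dataset.labels.copy(),
                        sampling_rate=dataset.sampling_rate,
                        channel_names=list(dataset.channel_names),
                        role=dataset.role)
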