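"""LDA classification, the repeated cross-validated evaluation protocol, and
McNemar paired significance testing between CSP variants.

The protocol mirrors how robust spatial filtering is benchmarked: for each
outlier rate, artifacts are re-injected many times with fresh random positions;
within each repetition a stratified k-fold cross-validation fits the spatial
filters and the classifier on training folds only, and held-out predictions are
pooled across repetitions for trial-level paired testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import binomtest, chi2

from .csp import (
    DEFAULT_ALPHA_GRID,
    estimate_class_covariance,
    fit_csp_l1,
    solve_csp_l2,
    solve_csp_tr,
    tune_tr_alpha,
)
from .features import DEFAULT_BAND, DEFAULT_WINDOW, bandpass_epoch, feature_matrix
from .simulation import OutlierSpec, SyntheticConfig, generate_mi_dataset, inject_outliers
from .types import TrialDataset, VALID_METHODS, derive_seed

_RIDGE_COND = 1e12


@dataclass
class LdaModel:
    """Fisher linear discriminant: predict class 1 when ``w.x + b > 0``."""

    weights: np.ndarray
    bias: float
    classes: tuple = (1, 2)


@dataclass
class EvaluationResult:
    """One method's performance at one outlier rate across repetitions."""

    method: str
    outlier_rate: float
    accuracies: np.ndarray          # one entry per repetition
    predictions: np.ndarray         # held-out predictions pooled over repetitions
    truths: np.ndarray              # matching true labels

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd_accuracy(self) -> float:
        if len(self.accuracies) < 2:
            return 0.0
        return float(np.std(self.accuracies, ddof=1))


@dataclass
class McNemarResult:
    b: int                 # A correct, B wrong
    c: int                 # A wrong, B correct
    statistic: float
    p_value: float
    flavor: str            # "chi-square-corrected" | "exact-binomial"


def _fit_lda_arrays(X: np.ndarray, y: np.ndarray) -> LdaModel:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim == 1:
        X = X[:, None]
    present = set(np.unique(y))
    if present != {1, 2}:
        raise ValueError(f"empty class: need both classes 1 and 2, got {sorted(present)}")
    X1, X2 = X[y == 1], X[y == 2]
    m1, m2 = X1.mean(axis=0), X2.mean(axis=0)
    scatter = ((X1 - m1).T @ (X1 - m1)) + ((X2 - m2).T @ (X2 - m2))
    Sw = scatter / max(len(y) - 2, 1)  # pooled within-class covariance, ddof = N - 2
    d = Sw.shape[0]
    evals = np.linalg.eigvalsh(Sw)
    if evals.max() <= 0 or evals.min() <= evals.max() / _RIDGE_COND:
        ridge = 1e-10 * max(np.trace(Sw) / d, 1e-30)
        Sw = Sw + ridge * np.eye(d)
    w = np.linalg.solve(Sw, m1 - m2)
    bias = -0.5 * float(w @ (m1 + m2))
    if not np.all(np.isfinite(w)):
        raise ValueError("invalid data: LDA weights are non-finite")
    return LdaModel(weights=w, bias=bias)


def _predict_arrays(model: LdaModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    score = X @ model.weights + model.bias
    return np.where(score > 0, 1, 2)


def lda_fit(features) -> LdaModel:
    """Fit a Fisher LDA on a list of labelled :class:`FeatureVector` objects."""
    X = np.vstack([np.atleast_1d(f.values) for f in features])
    y = np.array([f.label for f in features])
    if any(v is None for v in y):
        raise ValueError("invalid data: feature vectors must carry labels")
    return _fit_lda_arrays(X, y.astype(int))


def lda_predict(model: LdaModel, features) -> np.ndarray:
    """Predict labels for FeatureVectors (or a raw feature array)."""
    if isinstance(features, np.ndarray):
        return _predict_arrays(model, features)
    X = np.vstack([np.atleast_1d(f.values) for f in features])
    return _predict_arrays(model, X)


def mcnemar_test(preds_a, preds_b, truth) -> McNemarResult:
    """Paired McNemar test on two classifiers' trial-level predictions.

    Uses the continuity-corrected chi-square statistic
    ``(max(|b - c| - 1, 0))^2 / (b + c)`` when the discordant count is at least
    25, otherwise an exact two-sided binomial test on ``(b, b + c, 1/2)``.
    """
    a = np.asarray(preds_a)
    bb = np.asarray(preds_b)
    t = np.asarray(truth)
    if not (a.shape == bb.shape == t.shape) or a.ndim != 1 or a.size < 1:
        raise ValueError("shape mismatch: predictions and truth must be equal-length 1-D")
    ok_a, ok_b = a == t, bb == t
    b = int(np.sum(ok_a & ~ok_b))
    c = int(np.sum(~ok_a & ok_b))
    n = b + c
    statistic = (max(abs(b - c) - 1, 0) ** 2 / n) if n > 0 else 0.0
    if n == 0:
        return McNemarResult(b=b, c=c, statistic=0.0, p_value=1.0, flavor="exact-binomial")
    if n >= 25:
        p = float(chi2.sf(statistic, df=1))
        flavor = "chi-square-corrected"
    else:
        p = float(binomtest(b, n, 0.5, alternative="two-sided").pvalue)
        flavor = "exact-binomial"
    return McNemarResult(b=b, c=c, statistic=float(statistic), p_value=min(p, 1.0),
                         flavor=flavor)


def _fit_method(method, C1, C2, n_pairs, alpha, l1_seed):
    if method == "csp_l2":
        return solve_csp_l2(C1, C2, n_pairs)
    if method == "csp_tr":
        return solve_csp_tr(C1, C2, alpha if alpha is not None else 0.0, n_pairs)
    return fit_csp_l1(C1, C2, n_pairs, seed=l1_seed)


def run_protocol(data, methods=VALID_METHODS, rates=(0.01, 0.02, 0.03, 0.04, 0.05),
                 repetitions: int = 50, folds: int = 5, n_pairs: int = 3,
                 seed: int = 0, band=DEFAULT_BAND, window=DEFAULT_WINDOW,
                 outlier_multiplier: float = 10.0, segment_duration: float = None,
                 alpha_grid=DEFAULT_ALPHA_GRID, tune_folds: int = 10,
                 trace_normalize: bool = False, normalize_features: bool = False):
    """Repeated outlier-injection / cross-validation benchmark of CSP variants.

    ``data`` is either a ``(train, test)`` pair of :class:`TrialDataset` or a
    :class:`SyntheticConfig` to generate one. Trials are band-passed and
    windowed once; then, for every rate and repetition, outliers are injected
    into the analyzed epochs at fresh random positions (seeded per repetition)
    and a stratified ``folds``-fold CV fits covariances, spatial filters and
    LDA on training folds only. Injecting after the band-pass is essential:
    the artifact's large mean offset would otherwise be removed by the filter
    and never reach the covariance estimates whose corruption is under study.
    The Tikhonov weight is re-tuned once per repetition on the training portion
    of the first fold. Covariances default to the raw (unnormalized) per-trial
    average, so a large-amplitude trial carries proportionally large weight;
    pass ``trace_normalize=True`` for the equalized variant. Returns one
    :class:`EvaluationResult` per (rate, method).
    """
    from sklearn.model_selection import StratifiedKFold

    methods = list(methods)
    for mth in methods:
        if mth not in VALID_METHODS:
            raise ValueError(f"invalid method: {mth!r}")
    if repetitions < 1 or folds < 2:
        raise ValueError("invalid parameter: repetitions >= 1 and folds >= 2 required")
    if isinstance(data, SyntheticConfig):
        train, test, _ = generate_mi_dataset(data)
    else:
        train, test = data

    fs = train.sampling_rate
    pre_train = TrialDataset(trials=[bandpass_epoch(t, fs, band, window)
                                     for t in train.trials],
                             labels=train.labels, sampling_rate=fs,
                             channel_names=list(train.channel_names), role="train")
    pre_test = TrialDataset(trials=[bandpass_epoch(t, fs, band, window)
                                    for t in test.trials],
                            labels=test.labels, sampling_rate=fs,
                            channel_names=list(test.channel_names), role="test")
    results = []
    for ri, rate in enumerate(rates):
        accs = {mth: [] for mth in methods}
        preds = {mth: [] for mth in methods}
        truths = []
        for rep in range(repetitions):
            spec = OutlierSpec(rate=float(rate), amplitude_sigma_multiplier=outlier_multiplier,
                               segment_duration=segment_duration,
                               seed=derive_seed(seed, ri, rep, 0))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                ctr, cte, _ = inject_outliers(pre_train, pre_test, spec)
            trials = ctr.trials + cte.trials
            labels = np.concatenate([ctr.labels, cte.labels])
            pooled = TrialDataset(trials=trials, labels=labels, sampling_rate=fs,
                                  channel_names=list(train.channel_names))

            skf = StratifiedKFold(n_splits=folds, shuffle=True,
                                  random_state=derive_seed(seed, ri, rep, 1))
            fold_splits = list(skf.split(np.zeros(len(labels)), labels))

            alpha = None
            if "csp_tr" in methods:
                alpha = tune_tr_alpha(pooled.subset(fold_splits[0][0]), alpha_grid,
                                      folds=tune_folds, n_pairs=n_pairs,
                                      seed=derive_seed(seed, ri, rep, 2),
                                      trace_normalize=trace_normalize,
                                      normalize_features=normalize_features)

            rep_preds = {mth: np.zeros(len(labels), dtype=int) for mth in methods}
            for fi, (tr_idx, te_idx) in enumerate(fold_splits):
                sub = pooled.subset(tr_idx)
                C1 = estimate_class_covariance(sub, 1, trace_normalize)
                C2 = estimate_class_covariance(sub, 2, trace_normalize)
                tr_trials = [trials[i] for i in tr_idx]
                te_trials = [trials[i] for i in te_idx]
                for mth in methods:
                    fset = _fit_method(mth, C1, C2, n_pairs, alpha,
                                       l1_seed=derive_seed(seed, ri, rep, 3, fi))
                    Xtr = feature_matrix(tr_trials, fset, normalize=normalize_features)
                    model = _fit_lda_arrays(Xtr, labels[tr_idx])
                    Xte = feature_matrix(te_trials, fset, normalize=normalize_features)
                    rep_preds[mth][te_idx] = _predict_arrays(model, Xte)
            for mth in methods:
                accs[mth].append(float(np.mean(rep_preds[mth] == labels)))
                preds[mth].append(rep_preds[mth])
            truths.append(labels)
        truth_all = np.concatenate(truths)
        for mth in methods:
            results.append(EvaluationResult(
                method=mth, outlier_rate=float(rate),
                accuracies=np.asarray(accs[mth]),
                predictions=np.concatenate(preds[mth]),
                truths=truth_all))
    return results


def results_to_frame(results):
    """Long-format table (method, rate, repetition, accuracy) for export/plots."""
    import pandas as pd

    rows = []
    for r in results:
        for rep, acc in enumerate(r.accuracies):
            rows.append({"method": r.method, "rate": r.outlier_rate,
                         "repetition": rep, "accuracy": acc})
    return pd.DataFrame(rows, columns=["method", "rate", "repetition", "accuracy"])


def results_to_tsv(results, path):
    results_to_frame(results).to_csv(path, sep="\t", index=False)
    return path


def mcnemar_summary(results, pairs):
    """McNemar tests on pooled held-out predictions for method pairs, per rate.

    ``pairs`` is an iterable of ``(method_a, method_b)``. Returns a dict keyed
    ``"a_vs_b@rate"`` with discordant counts, statistic, p-value and the two
    mean accuracies.
    """
    by_key = {(r.method, r.outlier_rate): r for r in results}
    rates = sorted({r.outlier_rate for r in results})
    out = {}
    for a, b in pairs:
        for rate in rates:
            ra, rb = by_key.get((a, rate)), by_key.get((b, rate))
            if ra is None or rb is None:
                continue
            mc = mcnemar_test(ra.predictions, rb.predictions, ra.truths)
            out[f"{a}_vs_{b}@{rate:g}"] = {
                "b": mc.b, "c": mc.c, "statistic": mc.statistic,
                "p_value": mc.p_value, "flavor": mc.flavor,
                f"mean_{a}": ra.mean_accuracy, f"mean_{b}": rb.mean_accuracy,
            }
    return out
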