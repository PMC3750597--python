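"""Common Spatial Patterns solved three ways: L2, Tikhonov-regularized, and L1-SVD.

CSP seeks spatial filters ``w`` maximizing the Rayleigh quotient
``w.T C1 w / w.T C2 w`` between the two class covariances. The L2 route solves
the generalized eigenproblem ``C1 w = lambda C2 w``; the Tikhonov route adds an
``alpha * ||w||^2`` penalty to the denominator; the L1 route extracts directions
of maximal L1 dispersion ``||w.T Y||_1`` from ``Y = C2^{-1} C1`` with a greedy
fixed-point iteration and orthogonal deflation, which damps the quadratic
amplification that large-amplitude outliers receive under the L2 objective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .types import (
    CovarianceMatrix,
    EigenProblem,
    SpatialFilterSet,
    TrialDataset,
    canonicalize_columns,
    canonicalize_sign,
    derive_seed,
)

#: Default Tikhonov weight grid, on trace-normalized covariances.
DEFAULT_ALPHA_GRID = (0.0, 1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 1e-1)

_CONDITION_LIMIT = 1e12


def estimate_class_covariance(dataset: TrialDataset, class_id: int,
                              trace_normalize: bool = True) -> CovarianceMatrix:
    """Average per-trial spatial covariance ``X X.T`` over one class.

    With ``trace_normalize`` each per-trial matrix is divided by its trace
    before averaging and the average is re-normalized to unit trace, making the
    estimate invariant to per-trial amplitude scaling.
    """
    if class_id not in (1, 2):
        raise ValueError(f"invalid parameter: class_id must be 1 or 2, got {class_id}")
    idx = dataset.class_indices(class_id)
    if idx.size == 0:
        raise ValueError(f"empty class: no trials with label {class_id}")
    acc = None
    for i in idx:
        X = np.asarray(dataset.trials[i], dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError(f"invalid data: non-finite values in trial {i}")
        S = X @ X.T
        if trace_normalize:
            tr = np.trace(S)
            if tr <= 0:
                raise ValueError(f"invalid data: zero-power trial {i}")
            S = S / tr
        acc = S if acc is None else acc + S
    C = acc / idx.size
    if trace_normalize:
        C = C / np.trace(C)
    C = 0.5 * (C + C.T)
    return CovarianceMatrix(matrix=C, n_trials_pooled=int(idx.size),
                            normalized=bool(trace_normalize))


def _as_matrix(C) -> np.ndarray:
    if isinstance(C, CovarianceMatrix):
        return np.asarray(C.matrix, dtype=float)
    return np.asarray(C, dtype=float)


def _check_pair(C1, C2):
    A, B = _as_matrix(C1), _as_matrix(C2)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("shape mismatch: covariance must be square")
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    return A, B


def _ridge_repair(C: np.ndarray) -> np.ndarray:
    """Add a tiny ridge when the covariance is numerically singular."""
    evals = np.linalg.eigvalsh(C)
    top = evals.max()
    if top <= 0 or evals.min() <= top / _CONDITION_LIMIT:
        d = C.shape[0]
        ridge = 1e-10 * max(np.trace(C), d * 1e-300) / d
        warnings.warn("covariance numerically singular; applying ridge repair",
                      RuntimeWarning, stacklevel=3)
        C = C + ridge * np.eye(d)
        evals = np.linalg.eigvalsh(C)
        if evals.min() <= evals.max() / _CONDITION_LIMIT:
            raise ValueError("singular covariance: not invertible after ridge repair")
    return C


def solve_csp_l2(C1, C2, n_pairs: int = 3, channel_names=None) -> SpatialFilterSet:
    """Classical CSP via the generalized eigenproblem ``C1 w = lambda C2 w``.

    Returns the ``n_pairs`` eigenvectors with the largest eigenvalues followed
    by the ``n_pairs`` with the smallest, each scaled so ``w.T C2 w = 1``.
    """
    A, B = _check_pair(C1, C2)
    d = A.shape[0]
    if not 1 <= n_pairs <= d // 2:
        raise ValueError(f"invalid parameter: n_pairs must be in [1, {d // 2}]")
    B = _ridge_repair(B)
    try:
        evals, evecs = scipy.linalg.eigh(A, B)
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError):
        raise ValueError("singular covariance: generalized eigendecomposition failed")
    hi = evecs[:, ::-1][:, :n_pairs]
    lo = evecs[:, :n_pairs]
    scores = np.concatenate([evals[::-1][:n_pairs], evals[:n_pairs]])
    W = canonicalize_columns(np.hstack([hi, lo]))
    return SpatialFilterSet(filters=W, scores=scores, method="csp_l2",
                            channel_names=channel_names)


def solve_csp_tr(C1, C2, alpha: float, n_pairs: int = 3,
                 channel_names=None) -> SpatialFilterSet:
    """Tikhonov-regularized CSP.

    The first half maximizes ``w.T C1 w / (w.T C2 w + alpha ||w||^2)``, the
    second half the same quotient with the class roles swapped. The penalty
    shrinks high-norm (spatially rough) filters.
    """
    if alpha < 0:
        raise ValueError("invalid parameter: alpha must be non-negative")
    A, B = _check_pair(C1, C2)
    d = A.shape[0]
    if not 1 <= n_pairs <= d // 2:
        raise ValueError(f"invalid parameter: n_pairs must be in [1, {d // 2}]")
    eye = np.eye(d)
    halves, scores = [], []
    for num, den in ((A, B), (B, A)):
        pen = _ridge_repair(den + alpha * eye)
        try:
            evals, evecs = scipy.linalg.eigh(num, pen)
        except (np.linalg.LinAlgError, scipy.linalg.LinAlgError):
            raise ValueError("singular covariance: generalized eigendecomposition failed")
        halves.append(evecs[:, ::-1][:, :n_pairs])
        scores.append(evals[::-1][:n_pairs])
    W = canonicalize_columns(np.hstack(halves))
    return SpatialFilterSet(filters=W, scores=np.concatenate(scores), method="csp_tr",
                            alpha=float(alpha), channel_names=channel_names)


@dataclass
class L1Direction:
    """One greedy L1 direction: the unit vector, its dispersion, and the trace."""

    w: np.ndarray
    objective: float
    n_iter: int
    converged: bool
    history: np.ndarray  # L1 objective after each accepted iterate


def l1_greedy_direction(Y, init="auto", tol: float = 1e-8, max_iter: int = 200,
                        rng=None) -> L1Direction:
    """Maximize ``||w.T Y||_1`` over unit vectors by the fixed-point iteration
    ``w <- Y sign(Y.T w) / ||.||``.

    The update never decreases the objective, so the iteration converges to a
    local maximum; a fixed point is detected when the (sign-canonicalized)
    iterate stops moving by more than ``tol``. Exact zero projections, which
    would make the sign pattern ambiguous, are broken by a tiny seeded random
    perturbation of ``w``.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("shape mismatch: Y must be 2-D")
    if not np.all(np.isfinite(Y)):
        raise ValueError("invalid data: non-finite values in Y")
    if np.linalg.norm(Y) == 0:
        raise ValueError("degenerate input: Y is all zero")
    if tol <= 0:
        raise ValueError("invalid parameter: tol must be positive")
    if max_iter < 1:
        raise ValueError("invalid parameter: max_iter must be >= 1")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(0 if rng is None else int(rng))

    if isinstance(init, str) and init == "auto":
        U, _, _ = np.linalg.svd(Y, full_matrices=False)
        w = U[:, 0]
    else:
        w = np.asarray(init, dtype=float)
        nrm = np.linalg.norm(w)
        if nrm == 0:
            raise ValueError("invalid parameter: init vector must be non-zero")
        w = w / nrm
    w = canonicalize_sign(w)

    history = [float(np.abs(w @ Y).sum())]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = w @ Y
        if np.any(np.abs(p) < 1e-12):
            pert = rng.normal(size=w.shape)
            pert *= 1e-6 / np.linalg.norm(pert)
            w = canonicalize_sign((w + pert) / np.linalg.norm(w + pert))
            history.append(float(np.abs(w @ Y).sum()))
            continue
        w_new = Y @ np.sign(p)
        nrm = np.linalg.norm(w_new)
        if nrm == 0:  # sign pattern cancels exactly; break the tie and retry
            pert = rng.normal(size=w.shape)
            pert *= 1e-6 / np.linalg.norm(pert)
            w = canonicalize_sign((w + pert) / np.linalg.norm(w + pert))
            history.append(float(np.abs(w @ Y).sum()))
            continue
        w_new = canonicalize_sign(w_new / nrm)
        history.append(float(np.abs(w_new @ Y).sum()))
        delta = np.linalg.norm(w_new - w)
        w = w_new
        if delta < tol:
            converged = True
            break
    return L1Direction(w=w, objective=history[-1], n_iter=it,
                       converged=converged, history=np.asarray(history))


def l1_svd(Y, k: int, tol: float = 1e-8, max_iter: int = 200, rng=None) -> EigenProblem:
    """Extract ``k`` orthonormal L1-dispersion directions by greedy deflation.

    After each direction ``w`` the data matrix is deflated by
    ``Y <- Y - w (w.T Y)`` so later directions live in the orthogonal
    complement. Scores are ``||w.T Y||_1`` against the ORIGINAL matrix; greedy
    deflation does not guarantee they are non-increasing.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("shape mismatch: Y must be 2-D")
    d = Y.shape[0]
    if not 1 <= k <= d:
        raise ValueError(f"rank: k must be in [1, {d}], got {k}")
    if np.linalg.norm(Y) == 0:
        raise ValueError("degenerate input: Y is all zero")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(0 if rng is None else int(rng))

    scale = np.linalg.norm(Y)
    Ydef = Y.copy()
    cols = []
    for _ in range(k):
        Wmat = np.column_stack(cols) if cols else None
        if np.linalg.norm(Ydef) < 1e-12 * scale:
            w = _complement_vector(Wmat, d)
        else:
            w = l1_greedy_direction(Ydef, tol=tol, max_iter=max_iter, rng=rng).w
            if Wmat is not None:  # numerical re-orthogonalization
                w = w - Wmat @ (Wmat.T @ w)
                nrm = np.linalg.norm(w)
                if nrm < 1e-10:
                    w = _complement_vector(Wmat, d)
                else:
                    w = canonicalize_sign(w / nrm)
        cols.append(w)
        Ydef = Ydef - np.outer(w, w @ Ydef)
    W = np.column_stack(cols)
    V = W.T @ Y
    scores = np.abs(V).sum(axis=1)
    return EigenProblem(Y=Y, W=W, V=V, scores=scores)


def _complement_vector(Wmat, d: int) -> np.ndarray:
    """A unit vector orthogonal to the columns of ``Wmat`` (any one, deterministically)."""
    if Wmat is None:
        v = np.zeros(d)
        v[0] = 1.0
        return v
    ns = scipy.linalg.null_space(Wmat.T)
    return canonicalize_sign(ns[:, 0])


def fit_csp_l1(C1, C2, n_pairs: int = 3, mode: str = "literal", tol: float = 1e-8,
               max_iter: int = 200, seed: int = 0, channel_names=None) -> SpatialFilterSet:
    """L1-SVD-CSP: robust spatial filters from L1 dispersion of ``Y = C2^{-1} C1``.

    The default ``"literal"`` mode runs the L1 deflation directly on the
    (generally non-symmetric) matrix ``C2^{-1} C1`` for the class-1 half and on
    ``C1^{-1} C2`` for the class-2 half. The ``"whitened"`` mode instead runs it
    on the symmetric whitened covariance ``C2^{-1/2} C1 C2^{-1/2}`` and maps the
    directions back through the whitener; its filters are not orthonormal in
    sensor space.
    """
    A, B = _check_pair(C1, C2)
    d = A.shape[0]
    if not 1 <= n_pairs <= d // 2:
        raise ValueError(f"invalid parameter: n_pairs must be in [1, {d // 2}]")
    if mode not in ("literal", "whitened"):
        raise ValueError(f"invalid parameter: mode {mode!r}")
    Arep = _ridge_repair(A)
    Brep = _ridge_repair(B)
    halves, scores = [], []
    if mode == "literal":
        for num, den in ((A, Brep), (B, Arep)):
            Y = np.linalg.solve(den, num)
            ep = l1_svd(Y, n_pairs, tol=tol, max_iter=max_iter,
                        rng=np.random.default_rng(derive_seed(seed, len(halves))))
            halves.append(ep.W)
            scores.append(ep.scores)
    else:
        for num, den in ((A, Brep), (B, Arep)):
            evals, evecs = np.linalg.eigh(den)
            P = evecs @ np.diag(1.0 / np.sqrt(evals)) @ evecs.T  # den^{-1/2}
            S = P @ num @ P
            ep = l1_svd(S, n_pairs, tol=tol, max_iter=max_iter,
                        rng=np.random.default_rng(derive_seed(seed, len(halves))))
            Wh = P @ ep.W
            halves.append(Wh / np.linalg.norm(Wh, axis=0, keepdims=True))
            scores.append(ep.scores)
    W = canonicalize_columns(np.hstack(halves))
    return SpatialFilterSet(filters=W, scores=np.concatenate(scores),
                            method="csp_l1svd", channel_names=channel_names)


def tune_tr_alpha(train: TrialDataset, alpha_grid=DEFAULT_ALPHA_GRID, folds: int = 10,
                  n_pairs: int = 3, seed: int = 0, trace_normalize: bool = True,
                  normalize_features: bool = False) -> float:
    """Pick the Tikhonov weight by stratified cross-validation on the training set.

    The full TR-CSP + log-variance + LDA pipeline is refit inside every fold;
    the grid value with the highest mean held-out accuracy wins, ties going to
    the smaller alpha.
    """
    from sklearn.model_selection import StratifiedKFold

    from .evaluation import _fit_lda_arrays, _predict_arrays
    from .features import feature_matrix

    grid = sorted(float(a) for a in alpha_grid)
    if not grid:
        raise ValueError("invalid parameter: empty alpha grid")
    if len(grid) == 1:
        return grid[0]
    for c in (1, 2):
        if train.class_indices(c).size < folds:
            raise ValueError(f"invalid parameter: class {c} has fewer trials than folds")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % (2 ** 31))
    accs = np.zeros(len(grid))
    for tr_idx, te_idx in skf.split(np.zeros(train.n_trials), train.labels):
        sub = train.subset(tr_idx)
        C1 = estimate_class_covariance(sub, 1, trace_normalize)
        C2 = estimate_class_covariance(sub, 2, trace_normalize)
        for gi, alpha in enumerate(grid):
            fset = solve_csp_tr(C1, C2, alpha, n_pairs)
            Xtr = feature_matrix([train.trials[i] for i in tr_idx], fset,
                                 normalize=normalize_features)
            model = _fit_lda_arrays(Xtr, train.labels[tr_idx])
            Xte = feature_matrix([train.trials[i] for i in te_idx], fset,
                                 normalize=normalize_features)
            pred = _predict_arrays(model, Xte)
            accs[gi] += np.mean(pred == train.labels[te_idx])
    best = int(np.argmax(accs))  # argmax returns the first (smallest-alpha) maximum
    return grid[best]
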