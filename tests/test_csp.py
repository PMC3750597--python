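import numpy as np
import pytest
import scipy.linalg

from robustcsp import (
    TrialDataset,
    estimate_class_covariance,
    solve_csp_l2,
    solve_csp_tr,
    tune_tr_alpha,
)
from robustcsp.features import preprocess_dataset
from robustcsp.simulation import SyntheticConfig, generate_mi_dataset

from conftest import make_dataset, random_spd


def _dataset_from_trials(trials, labels, fs=100.0):
    return TrialDataset(trials=trials, labels=np.asarray(labels), sampling_rate=fs)


class TestClassCovariance:
    def test_identity_trial(self):
        ds = _dataset_from_trials([np.eye(2)], [1])
        cov = estimate_class_covariance(ds, 1, trace_normalize=False)
        np.testing.assert_allclose(cov.matrix, np.eye(2))
        cov_n = estimate_class_covariance(ds, 1, trace_normalize=True)
        np.testing.assert_allclose(cov_n.matrix, np.diag([0.5, 0.5]))

    def test_hand_computed_rank_one_trial(self):
        X = np.array([[1.0, 2.0, 3.0], [0.0, 0.0, 0.0]])
        ds = _dataset_from_trials([X], [1])
        cov = estimate_class_covariance(ds, 1, trace_normalize=False)
        np.testing.assert_allclose(cov.matrix, [[14.0, 0.0], [0.0, 0.0]])

    def test_rank_one_trial_normalized_fails_validation_free(self):
        X = np.array([[1.0, 2.0, 3.0], [0.0, 0.0, 0.0]])
        ds = _dataset_from_trials([X], [1])
        cov = estimate_class_covariance(ds, 1, trace_normalize=True)
        np.testing.assert_allclose(cov.matrix, [[1.0, 0.0], [0.0, 0.0]], atol=1e-15)

    def test_duplicate_trials_idempotent(self, rng):
        X = rng.normal(size=(3, 40))
        one = estimate_class_covariance(_dataset_from_trials([X], [1]), 1)
        two = estimate_class_covariance(_dataset_from_trials([X, X.copy()], [1, 1]), 1)
        np.testing.assert_allclose(one.matrix, two.matrix, rtol=1e-12)

    def test_empty_class_raises(self, rng):
        ds = _dataset_from_trials([rng.normal(size=(3, 10))], [1])
        with pytest.raises(ValueError, match="empty class"):
            estimate_class_covariance(ds, 2)

    def test_symmetric_psd_unit_trace(self, rng):
        ds = make_dataset(rng)
        cov = estimate_class_covariance(ds, 1, trace_normalize=True)
        assert abs(np.trace(cov.matrix) - 1.0) < 1e-10
        evals = np.linalg.eigvalsh(cov.matrix)
        assert evals.min() >= -1e-10 * evals.max()


class TestCspL2:
    def test_diagonal_pair_eigenpairs_read_off(self):
        fset = solve_csp_l2(np.diag([2.0, 1.0]), np.diag([1.0, 2.0]), n_pairs=1)
        np.testing.assert_allclose(fset.scores, [2.0, 0.5], atol=1e-12)
        # w'C2w = 1 scaling: e1 / 1 and e2 / sqrt(2)
        np.testing.assert_allclose(np.abs(fset.filters[:, 0]), [1.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(np.abs(fset.filters[:, 1]), [0.0, 1 / np.sqrt(2)],
                                   atol=1e-12)

    def test_equal_covariances_unit_eigenvalues(self, rng):
        C = random_spd(rng, 4)
        fset = solve_csp_l2(C, C, n_pairs=2)
        np.testing.assert_allclose(fset.scores, np.ones(4), atol=1e-10)

    @pytest.mark.parametrize("dim", [2, 4, 8, 16])
    def test_simultaneous_diagonalization(self, rng, dim):
        C1, C2 = random_spd(rng, dim), random_spd(rng, dim)
        fset = solve_csp_l2(C1, C2, n_pairs=dim // 2)
        W = fset.filters
        np.testing.assert_allclose(W.T @ C2 @ W, np.eye(dim), atol=1e-8)
        off = W.T @ C1 @ W - np.diag(np.diag(W.T @ C1 @ W))
        assert np.abs(off).max() < 1e-8

    def test_residual_against_independent_eigendecomposition(self, rng):
        C1, C2 = random_spd(rng, 4), random_spd(rng, 4)
        fset = solve_csp_l2(C1, C2, n_pairs=2)
        for w, lam in zip(fset.filters.T, fset.scores):
            res = np.linalg.norm(C1 @ w - lam * (C2 @ w))
            assert res < 1e-8 * np.linalg.norm(C1 @ w)
        # eigenvalues agree with a plain eig of C2^{-1} C1
        oracle = np.sort(np.linalg.eigvals(np.linalg.solve(C2, C1)).real)
        np.testing.assert_allclose(sorted(fset.scores),
                                   np.concatenate([oracle[:2], oracle[-2:]]),
                                   rtol=1e-8)

    def test_eigenvalue_invariance_under_congruence(self, rng):
        C1, C2 = random_spd(rng, 5), random_spd(rng, 5)
        T = rng.normal(size=(5, 5))
        while abs(np.linalg.det(T)) < 1e-3:
            T = rng.normal(size=(5, 5))
        a = solve_csp_l2(C1, C2, 2).scores
        b = solve_csp_l2(T @ C1 @ T.T, T @ C2 @ T.T, 2).scores
        np.testing.assert_allclose(a, b, rtol=1e-8)

    def test_shape_and_pair_count_errors(self, rng):
        C = random_spd(rng, 4)
        with pytest.raises(ValueError, match="shape"):
            solve_csp_l2(C, random_spd(rng, 3), 1)
        with pytest.raises(ValueError, match="n_pairs"):
            solve_csp_l2(C, C, 3)

    def test_singular_covariance_ridge_repair_warns(self, rng):
        C1 = random_spd(rng, 3)
        C2 = np.diag([1.0, 1.0, 0.0])  # exactly singular
        with pytest.warns(RuntimeWarning, match="ridge repair"):
            fset = solve_csp_l2(C1, C2, 1)
        assert np.all(np.isfinite(fset.filters))


class TestCspTr:
    def test_alpha_zero_matches_l2(self, rng):
        C1, C2 = random_spd(rng, 4), random_spd(rng, 4)
        l2 = solve_csp_l2(C1, C2, 2)
        tr = solve_csp_tr(C1, C2, 0.0, 2)
        for j in range(4):
            a = l2.filters[:, j] / np.linalg.norm(l2.filters[:, j])
            b = tr.filters[:, j] / np.linalg.norm(tr.filters[:, j])
            assert abs(abs(a @ b) - 1.0) < 1e-6

    def test_huge_alpha_gives_plain_eigenvectors(self, rng):
        C1, C2 = random_spd(rng, 4), random_spd(rng, 4)
        alpha = 1e9 * np.trace(C2)
        tr = solve_csp_tr(C1, C2, alpha, 1)
        _, v1 = np.linalg.eigh(C1)
        _, v2 = np.linalg.eigh(C2)
        first = tr.filters[:, 0] / np.linalg.norm(tr.filters[:, 0])
        second = tr.filters[:, 1] / np.linalg.norm(tr.filters[:, 1])
        assert abs(abs(first @ v1[:, -1]) - 1.0) < 1e-4
        assert abs(abs(second @ v2[:, -1]) - 1.0) < 1e-4

    def test_penalized_residual(self, rng):
        C1, C2 = random_spd(rng, 4), random_spd(rng, 4)
        alpha = 0.1
        tr = solve_csp_tr(C1, C2, alpha, 2)
        I = np.eye(4)
        for j in range(2):
            w, lam = tr.filters[:, j], tr.scores[j]
            res = np.linalg.norm(C1 @ w - lam * ((C2 + alpha * I) @ w))
            assert res < 1e-8 * np.linalg.norm(C1 @ w)

    def test_negative_alpha_rejected(self, rng):
        C = random_spd(rng, 4)
        with pytest.raises(ValueError, match="invalid parameter"):
            solve_csp_tr(C, C, -0.1, 1)


class TestScaleEquivariance:
    def test_filter_directions_invariant_to_amplitude_scaling(self, rng):
        from robustcsp import fit_csp_l1

        ds = make_dataset(rng, n_trials=16, n_channels=4, n_samples=60)
        scaled = TrialDataset(trials=[7.3 * t for t in ds.trials], labels=ds.labels,
                              sampling_rate=ds.sampling_rate)
        for fit in (lambda a, b: solve_csp_l2(a, b, 2),
                    lambda a, b: solve_csp_tr(a, b, 0.01, 2),
                    lambda a, b: fit_csp_l1(a, b, 2)):
            covs = [
                (estimate_class_covariance(d, 1, True), estimate_class_covariance(d, 2, True))
                for d in (ds, scaled)
            ]
            f_ref = fit(*covs[0])
            f_scl = fit(*covs[1])
            for j in range(f_ref.filters.shape[1]):
                a = f_ref.filters[:, j] / np.linalg.norm(f_ref.filters[:, j])
                b = f_scl.filters[:, j] / np.linalg.norm(f_scl.filters[:, j])
                assert abs(abs(a @ b) - 1.0) < 1e-8


class TestTuneAlpha:
    def test_singleton_grid_short_circuits(self, rng):
        ds = make_dataset(rng, n_trials=4)
        assert tune_tr_alpha(ds, alpha_grid=[0.37], folds=10) == 0.37

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError, match="invalid parameter"):
            tune_tr_alpha(make_dataset(rng), alpha_grid=[], folds=2)

    def test_clean_separable_data_prefers_no_penalty(self):
        wins = 0
        for s in range(20):
            cfg = SyntheticConfig(n_channels=8, n_trials_per_class=15,
                                  class_variance_ratio=8.0, snr=10.0,
                                  n_background_sources=4, mixing_seed=s,
                                  noise_seed=s + 50)
            train, _, _ = generate_mi_dataset(cfg)
            pre = preprocess_dataset(train)
            if tune_tr_alpha(pre, folds=5, n_pairs=2, seed=s) == 0.0:
                wins += 1
        assert wins > 10

    def test_deterministic_under_fixed_seed(self, small_config):
        train, _, _ = generate_mi_dataset(small_config)
        pre = preprocess_dataset(train)
        a = tune_tr_alpha(pre, folds=5, n_pairs=2, seed=9)
        b = tune_tr_alpha(pre, folds=5, n_pairs=2, seed=9)
        assert a == b
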