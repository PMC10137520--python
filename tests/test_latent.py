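"""Latent-variable machinery: PCA, PLS1, cross-validation, VIP, duplex."""

import numpy as np
import pytest

from procmon.latent import (
    CVScheme,
    duplex_split,
    fit_pca,
    fit_pls,
    rmsecv,
    rmsep,
    select_pca_components,
    venetian_blind_folds,
    vip_scores,
)


class TestPCA:
    def test_rank_one_matrix_fully_explained_by_one_component(self, rng):
        X = np.outer(rng.normal(size=9), rng.normal(size=6))
        X -= X.mean(axis=0)
        model = fit_pca(X, 1)
        assert model.explained_variance_pct[0] == pytest.approx(100.0)
        assert np.allclose(X - model.scores @ model.loadings.T, 0.0, atol=1e-10)

    def test_full_rank_reconstruction_identity(self, rng):
        X = rng.normal(size=(8, 5))
        X -= X.mean(axis=0)
        model = fit_pca(X, 5)
        assert np.max(np.abs(model.scores @ model.loadings.T - X)) < 1e-10

    def test_loadings_orthonormal_and_variances_nonincreasing(self, rng):
        X = rng.normal(size=(20, 7))
        X -= X.mean(axis=0)
        model = fit_pca(X, 5)
        assert np.allclose(model.loadings.T @ model.loadings, np.eye(5), atol=1e-10)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)

    def test_eigenvalues_match_covariance_eigendecomposition(self, rng):
        X = rng.normal(size=(5, 4))
        X -= X.mean(axis=0)
        model = fit_pca(X, 4)
        cov_eigs = np.sort(np.linalg.eigvalsh(np.cov(X, rowvar=False)))[::-1]
        assert np.max(np.abs(model.eigenvalues - cov_eigs[:4])) < 1e-8

    def test_score_variances_equal_eigenvalues(self, rng):
        X = rng.normal(size=(25, 6))
        X -= X.mean(axis=0)
        model = fit_pca(X, 4)
        assert np.allclose(model.scores.var(axis=0, ddof=1), model.eigenvalues)

    def test_rejects_zero_components(self, rng):
        with pytest.raises(ValueError):
            fit_pca(rng.normal(size=(4, 4)), 0)


class TestVenetianBlinds:
    def test_ten_samples_ten_splits_are_ordered_singletons(self):
        assert np.array_equal(venetian_blind_folds(10, 10), np.arange(10))

    def test_23_samples_fold_sizes(self):
        folds = venetian_blind_folds(23, 10)
        sizes = [int(np.sum(folds == k)) for k in range(10)]
        assert sizes == [3, 3, 3, 2, 2, 2, 2, 2, 2, 2]

    def test_every_index_in_exactly_one_fold(self):
        folds = venetian_blind_folds(57, 10)
        assert folds.size == 57
        assert set(folds) == set(range(10))

    def test_rejects_more_splits_than_samples(self):
        with pytest.raises(ValueError):
            venetian_blind_folds(5, 10)


class TestComponentSelection:
    def test_recovers_planted_rank(self, rng):
        X = rng.normal(size=(60, 2)) @ rng.normal(size=(2, 40))
        assert select_pca_components(X, 5)[0] == 2

    def test_pure_noise_selects_one(self):
        X = np.random.default_rng(0).normal(size=(60, 200))
        assert select_pca_components(X, 5)[0] == 1

    def test_invariant_to_column_permutation(self, rng):
        X = rng.normal(size=(50, 30))
        X[:, :3] += 5 * rng.normal(size=(50, 3))
        perm = rng.permutation(30)
        assert select_pca_components(X, 4)[0] == select_pca_components(X[:, perm], 4)[0]


class TestPLS:
    def test_exact_linear_response_fits_to_zero_residual(self, rng):
        X = rng.normal(size=(15, 4))
        beta = rng.normal(size=4)
        y = X @ beta
        model = fit_pls(X, y, 4)
        assert np.max(np.abs(model.predict(X) - y)) < 1e-8

    def test_univariate_predictor_matches_ols_slope(self, rng):
        x = rng.normal(size=(30, 1))
        y = 2.5 * x[:, 0] + rng.normal(0, 0.1, 30)
        model = fit_pls(x, y, 1)
        xc = x[:, 0] - x[:, 0].mean()
        yc = y - y.mean()
        slope = (xc @ yc) / (xc @ xc)
        assert model.regression_vector[0] == pytest.approx(slope, abs=1e-10)

    def test_full_rank_equals_minimum_norm_least_squares(self, rng):
        X = rng.normal(size=(20, 8))
        y = rng.normal(size=20)
        model = fit_pls(X, y, 8)
        Xc = X - X.mean(axis=0)
        B = np.linalg.pinv(Xc) @ (y - y.mean())
        assert np.max(np.abs(model.regression_vector - B)) < 1e-6

    def test_regression_vector_equals_sequential_deflation(self, rng):
        X = rng.normal(size=(25, 10))
        y = X @ rng.normal(size=10) + rng.normal(0, 0.3, 25)
        model = fit_pls(X, y, 5)
        Xc = X - X.mean(axis=0)
        yhat_seq = np.zeros(25)
        Xd = Xc.copy()
        for a in range(5):
            t = Xd @ model.x_weights[:, a]
            yhat_seq += t * model.y_loadings[a]
            Xd -= np.outer(t, model.x_loadings[:, a])
        assert np.max(np.abs(Xc @ model.regression_vector - yhat_seq)) < 1e-8

    def test_score_vectors_mutually_orthogonal(self, rng):
        X = rng.normal(size=(30, 12))
        y = X @ rng.normal(size=12) + rng.normal(0, 0.5, 30)
        T = fit_pls(X, y, 6).x_scores
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-8

    def test_training_rmse_nonincreasing_in_components(self, rng):
        X = rng.normal(size=(25, 8))
        y = X @ rng.normal(size=8) + rng.normal(0, 0.2, 25)
        errs = [
            np.sqrt(np.mean((fit_pls(X, y, a).predict(X) - y) ** 2)) for a in (1, 3, 5, 8)
        ]
        assert np.all(np.diff(errs) <= 1e-10)

    def test_matches_sklearn_reference(self, rng):
        """Independent cross-check against an established implementation."""
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(30, 10))
        y = X @ rng.normal(size=10) + rng.normal(0, 0.3, 30)
        ours = fit_pls(X, y, 4)
        ref = sklearn.PLSRegression(n_components=4, scale=False).fit(X, y)
        assert np.max(np.abs(ref.predict(X).ravel() - ours.predict(X))) < 1e-8

    def test_rejects_components_beyond_rank(self, rng):
        X = rng.normal(size=(10, 2)) @ rng.normal(size=(2, 6))
        with pytest.raises(ValueError):
            fit_pls(X, rng.normal(size=10), 4)


class TestCrossValidation:
    def test_noiseless_linear_response_gives_near_zero_rmsecv(self, rng):
        X = rng.normal(size=(40, 5))
        y = X @ rng.normal(size=5)
        errors, best = rmsecv(X, y, 5)
        assert errors[best - 1] < 1e-8

    def test_matches_explicit_fold_loop(self, rng):
        """Hand-looped two-fold cross-validation on a toy set."""
        X = rng.normal(size=(6, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + rng.normal(0, 0.1, 6)
        errors, _ = rmsecv(X, y, 2, CVScheme(n_splits=2))
        folds = np.arange(6) % 2
        sq = np.zeros(2)
        for k in (0, 1):
            tr, te = folds != k, folds == k
            for lv in (1, 2):
                m = fit_pls(X[tr], y[tr], lv)
                sq[lv - 1] += np.sum((m.predict(X[te]) - y[te]) ** 2)
        assert np.allclose(errors, np.sqrt(sq / 6), atol=1e-12)

    def test_rmsep_hand_cases(self, rng):
        X = rng.normal(size=(10, 3))
        y = X @ np.array([1.0, 1.0, 1.0])
        model = fit_pls(X, y, 3)
        assert rmsep(model, X, y) == pytest.approx(0.0, abs=1e-8)
        # planted residuals +1, -1
        y2 = model.predict(X[:2]) + np.array([1.0, -1.0])
        assert rmsep(model, X[:2], y2) == pytest.approx(1.0)
        # single sample: absolute residual
        y3 = model.predict(X[:1]) + 0.7
        assert rmsep(model, X[:1], y3) == pytest.approx(0.7)

    def test_rmsep_rejects_empty_test_set(self, rng):
        X = rng.normal(size=(10, 3))
        model = fit_pls(X, X @ np.ones(3), 2)
        with pytest.raises(ValueError):
            rmsep(model, np.empty((0, 3)), np.empty(0))


class TestVIP:
    def test_single_predictor_vip_is_one(self, rng):
        x = rng.normal(size=(20, 1))
        y = 3 * x[:, 0] + rng.normal(0, 0.1, 20)
        assert vip_scores(fit_pls(x, y, 1))[0] == pytest.approx(1.0)

    def test_mean_squared_vip_is_one(self, rng):
        X = rng.normal(size=(30, 14))
        y = X @ rng.normal(size=14) + rng.normal(0, 0.5, 30)
        vip = vip_scores(fit_pls(X, y, 5))
        assert np.mean(vip**2) == pytest.approx(1.0, abs=1e-10)

    def test_informative_variables_score_above_threshold(self, rng):
        X = rng.normal(size=(60, 20))
        y = 2 * X[:, 4] + rng.normal(0, 0.05, 60)
        vip = vip_scores(fit_pls(X, y, 2))
        assert np.argmax(vip) == 4
        assert vip[4] > 1.0


class TestDuplex:
    def test_203_samples_at_70_30_gives_142_61(self, rng):
        X = rng.normal(size=(203, 10))
        split = duplex_split(X, 0.7)
        assert len(split.calibration_indices) == 142
        assert len(split.test_indices) == 61

    def test_four_samples_half_split_partitions(self, rng):
        X = rng.normal(size=(4, 3))
        split = duplex_split(X, 0.5)
        cal, test = set(split.calibration_indices), set(split.test_indices)
        assert len(cal) == 2 and len(test) == 2
        assert cal | test == {0, 1, 2, 3}
        assert not cal & test

    def test_deterministic_partition(self, rng):
        X = rng.normal(size=(37, 6))
        a = duplex_split(X, 0.7)
        b = duplex_split(X, 0.7)
        assert np.array_equal(a.calibration_indices, b.calibration_indices)
        union = np.sort(np.concatenate([a.calibration_indices, a.test_indices]))
        assert np.array_equal(union, np.arange(37))

    def test_test_set_covers_data_better_than_random_splits(self):
        """Duplex spreads representatively: the test set's covering radius of
        the whole dataset (max over samples of the distance to the nearest
        test member) beats the random-split average on spectra-like data of
        low intrinsic dimension, in the mean over seeds."""
        from dataclasses import replace

        from procmon.synthetic import CampaignConfig, generate_campaign
        from procmon.preprocess import savitzky_golay

        def cover_radius(X, subset):
            d = np.linalg.norm(X[:, None] - X[subset][None], axis=2)
            return d.min(axis=1).max()

        ratios = []
        for seed in range(6):
            cfg = replace(
                CampaignConfig(), stop_schedule=(), n_time_points=150, seed=seed
            )
            X = savitzky_golay(generate_campaign(cfg).spectra).values
            split = duplex_split(X, 0.7)
            mc = np.random.default_rng(seed)
            rand = [
                cover_radius(X, mc.permutation(150)[105:]) for _ in range(20)
            ]
            ratios.append(cover_radius(X, split.test_indices) / np.mean(rand))
        assert np.mean(ratios) < 1.0

    def test_degenerate_ratios_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError):
            duplex_split(X, 0.999)
        with pytest.raises(ValueError):
            duplex_split(X[:3], 0.5)
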