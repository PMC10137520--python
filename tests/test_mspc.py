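"""Monitoring statistics, control limits, and chart behaviour."""

import numpy as np
import pytest
from scipy import stats

from procmon.mspc import (
    fit_mspc,
    flagged_episodes,
    hotelling_t2,
    monitor,
    noc_calibration_split,
    q_limit_box,
    q_limit_jackson_mudholkar,
    q_statistic,
    t2_limit,
    MSPCModel,
)
from procmon.latent import fit_pca
from procmon.preprocess import PreprocessState
from procmon.synthetic import CampaignConfig, generate_noc_block, inject_restart_anomaly


class TestHotellingT2:
    def test_model_center_scores_zero(self):
        assert hotelling_t2(np.zeros(3), np.ones(3)) == 0.0

    def test_hand_computed_value(self):
        assert hotelling_t2(np.array([2.0, 1.0]), np.array([4.0, 1.0])) == pytest.approx(2.0)

    def test_invariant_under_sign_flip(self, rng):
        scores = rng.normal(size=4)
        eigs = rng.random(4) + 0.1
        flipped = scores * np.array([1, -1, 1, -1])
        assert hotelling_t2(scores, eigs) == pytest.approx(hotelling_t2(flipped, eigs))

    def test_rejects_zero_eigenvalue(self):
        with pytest.raises(ValueError):
            hotelling_t2(np.ones(2), np.array([1.0, 0.0]))


class TestQStatistic:
    def _pca(self, rng):
        X = rng.normal(size=(30, 8))
        X -= X.mean(axis=0)
        return fit_pca(X, 3)

    def test_row_in_model_plane_has_zero_q(self, rng):
        pca = self._pca(rng)
        x = pca.loadings @ rng.normal(size=3)
        assert q_statistic(x, pca) == pytest.approx(0.0, abs=1e-18)

    def test_row_orthogonal_to_loadings_keeps_full_norm(self, rng):
        pca = self._pca(rng)
        x = rng.normal(size=8)
        x -= pca.loadings @ (pca.loadings.T @ x)
        assert q_statistic(x, pca) == pytest.approx(float(x @ x))

    def test_matches_direct_reconstruction_residual(self, rng):
        pca = self._pca(rng)
        x = rng.normal(size=8)
        resid = x - (x @ pca.loadings) @ pca.loadings.T
        assert abs(q_statistic(x, pca) - resid @ resid) < 1e-10

    def test_q_plus_t2_norm_decomposition(self, rng):
        pca = self._pca(rng)
        x = rng.normal(size=8)
        t = x @ pca.loadings
        assert x @ x == pytest.approx(q_statistic(x, pca) + float(t @ t), abs=1e-8)


class TestT2Limit:
    def test_monotone_decreasing_in_alpha(self):
        limits = [t2_limit(100, 4, a) for a in (0.01, 0.05, 0.1, 0.5)]
        assert np.all(np.diff(limits) < 0)

    def test_alpha_to_one_limit_vanishes(self):
        assert t2_limit(100, 4, 1 - 1e-12) == pytest.approx(0.0, abs=1e-4)

    def test_matches_monte_carlo_new_observation_percentile(self):
        """T² of new multivariate-normal observations, scored against
        eigenvalues estimated from a finite NOC calibration set, exceeds the
        F-form limit at the nominal 5% rate."""
        rng = np.random.default_rng(2024)
        n, a = 294, 4
        limit = t2_limit(n, a, 0.05)
        exceed = 0
        trials = 400
        new_per_trial = 50
        for _ in range(trials):
            cal = rng.normal(size=(n, a))
            cal -= cal.mean(axis=0)
            eigs = cal.var(axis=0, ddof=1)
            new = rng.normal(size=(new_per_trial, a))
            t2 = np.sum(new**2 / eigs, axis=1)
            exceed += int(np.sum(t2 > limit))
        rate = exceed / (trials * new_per_trial)
        # 3 sigma binomial band around 0.05 for 20000 draws
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / (trials * new_per_trial))

    def test_rejects_too_few_samples(self):
        with pytest.raises(ValueError):
            t2_limit(4, 4, 0.05)


class TestQLimits:
    def test_all_zero_eigenvalues_give_zero_limits(self):
        assert q_limit_jackson_mudholkar(np.zeros(5)) == 0.0
        assert q_limit_box(np.zeros(5)) == 0.0

    def test_jackson_mudholkar_matches_simulation(self):
        """Empirical 95th percentile of Q = Σ λ_i z_i² within 5% of the limit."""
        rng = np.random.default_rng(7)
        eigs = np.array([1.0, 0.5, 0.25, 0.1, 0.05])
        limit = q_limit_jackson_mudholkar(eigs, 0.05)
        draws = rng.normal(size=(100_000, 5))
        q = (draws**2 * eigs).sum(axis=1)
        emp = np.quantile(q, 0.95)
        assert abs(limit - emp) / emp < 0.05

    def test_jackson_mudholkar_monotone_in_eigenvalues(self):
        eigs = np.array([1.0, 0.5, 0.2])
        base = q_limit_jackson_mudholkar(eigs)
        bigger = q_limit_jackson_mudholkar(eigs + np.array([0.5, 0, 0]))
        assert bigger > base

    def test_box_single_eigenvalue_is_scaled_chi2(self):
        lam = 0.7
        assert q_limit_box(np.array([lam]), 0.05) == pytest.approx(
            lam * stats.chi2.ppf(0.95, 1)
        )

    def test_box_equal_eigenvalues_collapse(self):
        lam, k = 0.3, 6
        limit = q_limit_box(np.full(k, lam), 0.05)
        assert limit == pytest.approx(lam * stats.chi2.ppf(0.95, k))

    def test_methods_agree_on_decaying_spectrum(self):
        eigs = 2.0 ** -np.arange(8)
        jm = q_limit_jackson_mudholkar(eigs, 0.05)
        box = q_limit_box(eigs, 0.05)
        assert abs(jm - box) / jm < 0.10


@pytest.fixture(scope="module")
def noc_model():
    cfg = CampaignConfig(seed=21)
    block = generate_noc_block(294, cfg)
    return cfg, block, fit_mspc(block, 4)


class TestFitMonitor:
    def test_deterministic_limits(self, noc_model):
        cfg, block, model = noc_model
        again = fit_mspc(generate_noc_block(294, cfg), 4)
        assert again.t2_limit == model.t2_limit
        assert again.q_limit == model.q_limit

    def test_four_components_explain_study_level_variance(self, noc_model):
        _, _, model = noc_model
        assert model.pca.explained_variance_pct.sum() >= 93.0

    def test_calibration_self_exceedance_near_alpha(self, noc_model):
        _, block, model = noc_model
        points = monitor(block, model)
        for rates in (
            np.mean([p.exceeds_t2 for p in points]),
            np.mean([p.exceeds_q for p in points]),
        ):
            # binomial 3 sigma around 5% for 294 samples
            assert rates <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 294)

    def test_monitor_is_pure_and_reproducible(self, noc_model):
        _, block, model = noc_model
        first = monitor(block, model)
        second = monitor(block, model)
        assert [p.t2 for p in first] == [p.t2 for p in second]
        assert [p.q for p in first] == [p.q for p in second]

    def test_monitor_rejects_wrong_grid(self, noc_model):
        _, block, model = noc_model
        narrower = block.take(np.arange(10))
        from procmon.containers import SpectraBlock

        bad = SpectraBlock(
            narrower.timestamps, narrower.wavelengths[:-1], narrower.values[:, :-1]
        )
        with pytest.raises(ValueError):
            monitor(bad, model)

    def test_restart_sensitivity_on_centered_chart(self):
        """Amplitude shifts of 5x the channel noise are caught on Q with at
        least 95% sensitivity when amplitude and noise share a scale (charts
        on centered absorbance spectra)."""
        cfg = CampaignConfig(seed=7)
        noc = generate_noc_block(400, cfg)
        cal, test = noc.take(np.arange(294)), noc.take(np.arange(294, 400))
        model = fit_mspc(cal, 4, preprocess=PreprocessState(methods=["mean_center"]))
        min_base = min(b.base_amplitude for b in cfg.bands if b.restart_affected)
        scale = 5 * cfg.noise_sd / min_base
        anomalous = inject_restart_anomaly(test, np.arange(test.n_samples), scale, cfg.bands)
        points = monitor(anomalous, model)
        assert np.mean([p.exceeds_q for p in points]) >= 0.95


class TestEpisodes:
    def test_runs_found_with_min_length(self):
        flags = np.array([0, 1, 1, 1, 0, 1, 0, 1, 1, 0], dtype=bool)
        assert flagged_episodes(flags) == [(1, 4), (5, 6), (7, 9)]
        assert flagged_episodes(flags, min_length=2) == [(1, 4), (7, 9)]
        assert flagged_episodes(np.zeros(5, dtype=bool)) == []


class TestNOCSplit:
    def test_single_period_65_35(self):
        import pandas as pd

        ts = pd.date_range("2020-06-01", periods=100, freq="15s")
        split = noc_calibration_split(ts, [], 0.65)
        assert len(split.calibration_indices) == 65
        assert len(split.test_indices) == 35
        assert split.calibration_indices.max() < split.test_indices.min()

    def test_single_point_period_goes_to_calibration(self):
        import pandas as pd

        ts = pd.date_range("2020-06-01", periods=1, freq="15s")
        split = noc_calibration_split(ts, [], 0.65)
        assert list(split.calibration_indices) == [0]

    def test_per_period_temporal_contiguity(self):
        import pandas as pd

        ts = pd.date_range("2020-06-01", periods=50, freq="15s")
        stops = [(ts[20], ts[24])]
        split = noc_calibration_split(ts, stops, 0.65)
        cal = set(split.calibration_indices)
        test = set(split.test_indices)
        # stop points always in the test set
        assert set(range(20, 25)) <= test
        # within each period, calibration precedes test
        for period in (range(0, 20), range(25, 50)):
            cal_p = [i for i in period if i in cal]
            test_p = [i for i in period if i in test and not 20 <= i <= 24]
            if cal_p and test_p:
                assert max(cal_p) < min(test_p)

    def test_model_serialization_round_trip(self, tmp_path):
        cfg = CampaignConfig(seed=3)
        block = generate_noc_block(60, cfg)
        model = fit_mspc(block, 3)
        model.save(tmp_path / "m.yaml")
        reloaded = MSPCModel.load(tmp_path / "m.yaml")
        a = monitor(block, model)
        b = monitor(block, reloaded)
        assert np.allclose([p.t2 for p in a], [p.t2 for p in b])
        assert np.allclose([p.q for p in a], [p.q for p in b])
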