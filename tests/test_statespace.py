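"""Gompertz state-space denoising: likelihood, smoothing, recovery."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from marstab import (CommunityTimeSeries, DesignError,
                     GompertzStateSpaceModel, denoise_community,
                     fit_state_space, generate_dataset, scenario_preset)


def simulate_ssm(rng, n, m, a, c, tau2, obs_var, missing=()):
    """Simulate latent AR(1) states + replicated noisy observations."""
    x = np.empty(n)
    x[0] = rng.normal(a / (1 - c), np.sqrt(tau2 / (1 - c * c)))
    for t in range(1, n):
        x[t] = a + c * x[t - 1] + rng.normal(0.0, np.sqrt(tau2))
    y = x[:, None] + rng.normal(0.0, np.sqrt(obs_var), size=(n, m))
    for t, r in missing:
        y[t, r] = np.nan
    return x, y


def joint_mvn_loglik(y, a, c, tau2, obs_var):
    """Direct joint-normal density of all observed replicates.

    Independent of the Kalman recursion: builds the full covariance of
    the latent AR(1) path (stationary initial distribution) plus white
    observation noise and evaluates one multivariate-normal logpdf.
    """
    n, m = y.shape
    mean_x = np.empty(n)
    var_x = np.empty(n)
    mean_x[0] = a / (1 - c)
    var_x[0] = tau2 / (1 - c * c)
    for t in range(1, n):
        mean_x[t] = a + c * mean_x[t - 1]
        var_x[t] = c * c * var_x[t - 1] + tau2
    cov_x = np.empty((n, n))
    for s in range(n):
        for t in range(s, n):
            cov_x[s, t] = cov_x[t, s] = c ** (t - s) * var_x[s]
    idx = [(t, r) for t in range(n) for r in range(m)
           if not np.isnan(y[t, r])]
    mean = np.array([mean_x[t] for t, _ in idx])
    C = np.array([
        [cov_x[t1, t2] + (obs_var if (t1, r1) == (t2, r2) else 0.0)
         for (t2, r2) in idx]
        for (t1, r1) in idx
    ])
    obs = np.array([y[t, r] for t, r in idx])
    return multivariate_normal.logpdf(obs, mean, C, allow_singular=True)


class TestLikelihood:
    @pytest.mark.parametrize("n,m,missing", [
        (5, 1, ()),
        (8, 1, ((2, 0), (5, 0))),
        (6, 3, ((1, 0), (1, 1), (1, 2), (4, 1))),
        (4, 2, ()),
    ])
    def test_kalman_matches_brute_force_joint_density(self, rng, n, m,
                                                      missing):
        _, y = simulate_ssm(rng, n, m, a=1.0, c=0.6, tau2=0.2, obs_var=0.3,
                            missing=missing)
        model = GompertzStateSpaceModel(y)
        for a, c, tau2, ov in [(1.0, 0.6, 0.2, 0.3), (0.5, 0.9, 0.05, 0.6),
                               (2.0, -0.4, 0.4, 0.1)]:
            assert model.loglike(a, c, tau2, ov) == pytest.approx(
                joint_mvn_loglik(y, a, c, tau2, ov), abs=1e-8
            )

    def test_optimum_beats_a_surrounding_grid(self, rng):
        _, y = simulate_ssm(rng, 120, 1, a=2.0, c=0.8, tau2=0.1, obs_var=0.2)
        model = GompertzStateSpaceModel(y)
        fit = model.fit()
        best = fit.loglik
        for ft in np.geomspace(0.25, 4.0, 20):
            for fo in np.geomspace(0.25, 4.0, 20):
                ll = model.loglike(fit.a, fit.c, fit.tau2 * ft,
                                   fit.obs_var * fo)
                assert ll <= best + 1e-6


class TestSmoothing:
    def test_zero_obs_var_interpolates_exactly(self, rng):
        _, y = simulate_ssm(rng, 40, 1, a=1.0, c=0.7, tau2=0.2, obs_var=0.0)
        fit = fit_state_space(y, fix_obs_var=0.0)
        np.testing.assert_allclose(fit.smoothed_mean, y[:, 0], atol=1e-8)
        assert fit.obs_var == 0.0

    def test_interior_missing_day_has_inflated_variance(self, rng):
        _, y = simulate_ssm(rng, 5, 1, a=1.0, c=0.7, tau2=0.2, obs_var=0.1,
                            missing=((2, 0),))
        model = GompertzStateSpaceModel(y)
        _, sv = model.smooth(1.0, 0.7, 0.2, 0.1)
        assert sv[2] > sv[1] and sv[2] > sv[3]

    def test_interior_missing_day_matches_hand_recursion(self, rng):
        # forward-backward on a 5-point series, written out longhand
        a, c, tau2, ov = 1.0, 0.7, 0.2, 0.1
        _, y = simulate_ssm(rng, 5, 1, a=a, c=c, tau2=tau2, obs_var=ov,
                            missing=((2, 0),))
        mu = a / (1 - c)
        P = tau2 / (1 - c * c)
        fm, fv = [], []
        for t in range(5):
            if t:
                mu, P = a + c * mu, c * c * P + tau2
            if not np.isnan(y[t, 0]):
                K = P / (P + ov)
                mu, P = mu + K * (y[t, 0] - mu), P * (1 - K)
            fm.append(mu)
            fv.append(P)
        sm = [None] * 5
        sv = [None] * 5
        sm[4], sv[4] = fm[4], fv[4]
        for t in (3, 2, 1, 0):
            Pp = c * c * fv[t] + tau2
            J = fv[t] * c / Pp
            sm[t] = fm[t] + J * (sm[t + 1] - (a + c * fm[t]))
            sv[t] = fv[t] + J * J * (sv[t + 1] - Pp)
        model = GompertzStateSpaceModel(y)
        got_m, got_v = model.smooth(a, c, tau2, ov)
        np.testing.assert_allclose(got_m, sm, atol=1e-12)
        np.testing.assert_allclose(got_v, sv, atol=1e-12)


class TestFitting:
    def test_parameter_recovery(self):
        # median over replicate fits recovers the generating parameters
        truth = dict(a=2.0, c=0.8, tau2=0.1, obs_var=0.2)
        ests = []
        for seed in range(1, 13):
            rng = np.random.default_rng(seed)
            _, y = simulate_ssm(rng, 500, 1, **truth)
            fit = fit_state_space(y)
            ests.append((fit.a, fit.c, fit.tau2, fit.obs_var))
        med = np.median(np.asarray(ests), axis=0)
        assert med[1] == pytest.approx(truth["c"], abs=0.1)
        assert med[2] == pytest.approx(truth["tau2"], rel=0.2)
        assert med[3] == pytest.approx(truth["obs_var"], rel=0.2)

    def test_too_short_series_is_a_design_error(self):
        with pytest.raises(DesignError):
            fit_state_space(np.array([1.0, 2.0, np.nan]))

    def test_replicates_sharpen_obs_var(self, rng):
        _, y = simulate_ssm(rng, 200, 3, a=1.0, c=0.7, tau2=0.1, obs_var=0.3)
        fit = fit_state_space(y)
        assert fit.obs_var == pytest.approx(0.3, rel=0.35)
        assert fit.n_obs == 600


class TestDenoiseCommunity:
    def test_noiseless_input_is_returned_unchanged(self):
        data = generate_dataset(scenario_preset(1).params, n=40, m=1,
                                obs_var=0.0, missing_rate=0.0, seed=8)
        series = data.to_series()
        denoised, fits = denoise_community(series, fix_obs_var=0.0)
        np.testing.assert_allclose(denoised.log_abundance[:, :, 0],
                                   series.log_abundance[:, :, 0], atol=1e-7)

    def test_missing_cells_are_imputed(self):
        data = generate_dataset(scenario_preset(1).params, n=60, m=3,
                                obs_var=0.1, missing_rate=0.1, seed=9)
        series = data.to_series()
        assert series.missing_mask.any()
        denoised, fits = denoise_community(series)
        assert not denoised.missing_mask.any()
        assert denoised.m == 1
        assert denoised.state_variance.shape == (3, 60)
        assert len(fits) == 3

    def test_smoothing_beats_raw_observations(self):
        params = scenario_preset(1).params
        data = generate_dataset(params, n=100, m=3, obs_var=0.3,
                                missing_rate=0.0, seed=10)
        series = data.to_series()
        denoised, _ = denoise_community(series)
        truth = data.latent_log
        mse_smooth = np.mean((denoised.log_abundance[:, :, 0] - truth) ** 2)
        mse_raw = np.mean((series.replicate_mean() - truth) ** 2)
        assert mse_smooth < mse_raw

    def test_failures_name_the_taxon(self):
        x = np.full((2, 6, 1), np.nan)
        x[0, :, 0] = [1.0, 1.2, 1.1, 0.9, 1.05, 1.1]
        x[1, :2, 0] = [1.0, 1.0]   # too short after trimming
        series = CommunityTimeSeries("s", ["good", "bad"], np.arange(6), x)
        with pytest.raises(Exception, match="bad"):
            denoise_community(series)
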