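"""RPM/VPM persistence machinery and the counterfactual experiments."""

import numpy as np
import pytest
from scipy import stats

from marstab import (MARParameters, PersistenceSpec, ValidationError,
                     boost_growth, flip_interactions, rpm_curve,
                     stationary_mean, vpm_series)

from conftest import LN_TOTAL


class TestCounterfactualOperations:
    def test_flip_switches_the_reciprocal_pair_only(self, two_group_params):
        flipped = flip_interactions(two_group_params, 0, 1)
        assert flipped.B[0, 1] == pytest.approx(0.39)
        assert flipped.B[1, 0] == pytest.approx(-0.001)
        np.testing.assert_array_equal(np.diag(flipped.B),
                                      np.diag(two_group_params.B))
        np.testing.assert_array_equal(flipped.A, two_group_params.A)
        np.testing.assert_array_equal(flipped.Sigma, two_group_params.Sigma)

    def test_flip_is_an_involution(self, two_group_params):
        twice = flip_interactions(flip_interactions(two_group_params, 0, 1),
                                  0, 1)
        np.testing.assert_allclose(twice.B, two_group_params.B)

    def test_flip_of_zero_coefficients_is_identity(self):
        params = MARParameters(np.zeros(2), 0.5 * np.eye(2), np.eye(2))
        np.testing.assert_array_equal(flip_interactions(params, 0, 1).B,
                                      params.B)

    def test_flip_same_taxon_rejected(self, two_group_params):
        with pytest.raises(ValidationError):
            flip_interactions(two_group_params, 1, 1)

    def test_boost_scales_one_growth_rate(self, two_group_params):
        boosted = boost_growth(two_group_params, 0, 1.25)
        assert boosted.A[0] == pytest.approx(two_group_params.A[0] * 1.25)
        assert boosted.A[1] == two_group_params.A[1]
        np.testing.assert_array_equal(boosted.B, two_group_params.B)

    def test_boost_roundtrip_and_identity(self, two_group_params):
        same = boost_growth(two_group_params, 0, 1.0)
        np.testing.assert_array_equal(same.A, two_group_params.A)
        back = boost_growth(boost_growth(two_group_params, 1, 2.0), 1, 0.5)
        np.testing.assert_allclose(back.A, two_group_params.A)

    def test_boost_rejects_nonpositive_factor(self, two_group_params):
        with pytest.raises(ValidationError):
            boost_growth(two_group_params, 0, 0.0)


class TestRPM:
    def test_vanishing_threshold_gives_certain_persistence(self,
                                                           two_group_params):
        spec = PersistenceSpec(threshold=1e-12, horizon=5, n_traj=200)
        curve = rpm_curve(two_group_params, spec, seed=0)
        np.testing.assert_array_equal(curve.probabilities, 1.0)

    def test_deterministic_dominant_focal_persists(self, two_group_params):
        params = MARParameters(two_group_params.A, two_group_params.B,
                               np.zeros((2, 2)))
        # start focal 2 log units above the other group
        x0 = np.array([LN_TOTAL + 2.0, LN_TOTAL - 2.0])
        spec = PersistenceSpec(threshold=0.45, horizon=10, n_traj=10)
        curve = rpm_curve(params, spec, seed=0, x0=x0)
        np.testing.assert_array_equal(curve.probabilities, 1.0)

    def test_sign_flipped_two_group_model_persists_for_20_days(
            self, two_group_params):
        flipped = flip_interactions(two_group_params, 0, 1)
        spec = PersistenceSpec(threshold=0.45, horizon=20, n_traj=10_000)
        curve = rpm_curve(flipped, spec, seed=1,
                          x0=np.full(2, LN_TOTAL))
        np.testing.assert_array_equal(curve.probabilities, 1.0)

    def test_marginal_bounds_first_passage_from_above(self,
                                                      two_group_params):
        base = dict(threshold=0.45, horizon=20, n_traj=5000)
        marg = rpm_curve(two_group_params,
                         PersistenceSpec(mode="marginal", **base), seed=3)
        fp = rpm_curve(two_group_params,
                       PersistenceSpec(mode="first_passage", **base), seed=3)
        assert np.all(marg.probabilities >= fp.probabilities)
        assert np.all(np.diff(fp.probabilities) <= 0 + 1e-12)

    def test_day1_probability_matches_closed_form(self, two_group_params):
        spec = PersistenceSpec(threshold=0.45, horizon=1, n_traj=50_000)
        curve = rpm_curve(two_group_params, spec, seed=5)
        mu = stationary_mean(two_group_params)
        x0 = np.full(2, mu[0])
        m = two_group_params.A + two_group_params.B @ x0
        S = two_group_params.Sigma
        diff_mean = m[0] - m[1]
        diff_sd = np.sqrt(S[0, 0] + S[1, 1] - 2 * S[0, 1])
        cutoff = np.log(0.45 / 0.55)
        exact = 1.0 - stats.norm.cdf(cutoff, loc=diff_mean, scale=diff_sd)
        mc_se = np.sqrt(exact * (1 - exact) / spec.n_traj)
        assert curve.probabilities[0] == pytest.approx(exact, abs=3 * mc_se)

    def test_counterfactuals_restore_persistence(self, two_group_params):
        x0 = np.full(2, LN_TOTAL)
        spec = PersistenceSpec(threshold=0.45, horizon=20, n_traj=10_000)
        orig = rpm_curve(two_group_params, spec, seed=2)
        flip = rpm_curve(flip_interactions(two_group_params, 0, 1), spec,
                         seed=2, x0=x0)
        boost = rpm_curve(boost_growth(two_group_params, 0, 1.25), spec,
                          seed=2, x0=x0)
        # original: persistence decays from near-certainty
        assert orig.probabilities[0] > orig.probabilities[-1]
        assert orig.minimum() < 0.9
        # both interventions dominate the original curve everywhere
        assert np.all(flip.probabilities >= orig.probabilities)
        assert np.all(boost.probabilities >= orig.probabilities)

    def test_requires_two_groups(self):
        params = MARParameters(np.zeros(3), 0.5 * np.eye(3), np.eye(3))
        with pytest.raises(ValidationError):
            rpm_curve(params, PersistenceSpec(n_traj=10), seed=0)

    def test_seeded_reproducibility(self, two_group_params):
        spec = PersistenceSpec(n_traj=2000)
        a = rpm_curve(two_group_params, spec, seed=9)
        b = rpm_curve(two_group_params, spec, seed=9)
        np.testing.assert_array_equal(a.probabilities, b.probabilities)


class TestVPM:
    def test_safe_series_has_negligible_risk(self, two_group_params):
        # focal fluctuating far above the threshold: crash risk ~ 0
        n = 60
        rng = np.random.default_rng(0)
        X = np.vstack([
            LN_TOTAL + 3.0 + 0.05 * rng.standard_normal(n),
            LN_TOTAL - 3.0 + 0.05 * rng.standard_normal(n),
        ])
        spec = PersistenceSpec.vpm_defaults(n_traj=2000)
        days, risks = vpm_series(X, spec, fit_start=30, seed=1)
        assert np.all(risks <= 0.01)
        assert days[0] == 30 and days[-1] == n

    def test_declining_focal_gives_rising_risk(self):
        # deterministic downward trend crossing the threshold
        rhos = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 70
            trend = np.linspace(1.5, -0.3, n)
            X = np.vstack([
                LN_TOTAL + trend + 0.3 * rng.standard_normal(n),
                LN_TOTAL + 0.3 * rng.standard_normal(n),
            ])
            spec = PersistenceSpec.vpm_defaults(n_traj=500)
            days, risks = vpm_series(X, spec, fit_start=30, seed=seed)
            rho = stats.spearmanr(days, risks).statistic
            rhos.append(rho)
        assert np.median(rhos) > 0.8

    def test_seeded_reproducibility(self, two_group_params):
        X = np.vstack([
            np.full(40, LN_TOTAL + 1.0),
            np.full(40, LN_TOTAL - 1.0),
        ]) + np.random.default_rng(3).normal(0, 0.2, size=(2, 40))
        spec = PersistenceSpec.vpm_defaults(n_traj=500)
        r1 = vpm_series(X, spec, fit_start=20, seed=4)
        r2 = vpm_series(X, spec, fit_start=20, seed=4)
        np.testing.assert_array_equal(r1[1], r2[1])
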