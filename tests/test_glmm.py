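import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy.special import expit

import prevently as pv
from prevently._agq import AGQProblem, BinaryFamily, OrdinalFamily, theta_from_sigma
from prevently.glmm import (
    MixedModelSpec,
    build_design,
    fit_lagged_association,
    fit_mixed_logit,
    fit_mixed_ologit,
    joint_interaction_test,
    marginal_loglik,
    marginal_probability,
    predict_marginal_prob,
)
from prevently.synth import simulate_truth

ZERO = ((0.0, 0.0), (0.0, 0.0))


def toy_data(G=3, n_t=8, seed=1, ordinal=False):
    rng = np.random.default_rng(seed)
    gi = np.repeat(np.arange(G), n_t)
    t = np.tile(np.arange(n_t), G)
    z = (t >= n_t // 2).astype(float)
    X = np.column_stack([np.ones(G * n_t), t / 4.0, z])
    beta = np.array([0.3, -0.4, 0.5])
    sigma = np.array([[1.2, -0.3], [-0.3, 0.8]])
    b = rng.multivariate_normal([0, 0], sigma, size=G)
    eta = X @ beta + b[gi, 0] + b[gi, 1] * z
    if ordinal:
        X = X[:, 1:]
        beta = beta[1:]
        eta = X @ beta + b[gi, 0] + b[gi, 1] * z
        alpha = np.array([-0.4, 0.9])
        u = rng.random(G * n_t)
        y = np.where(
            u < expit(alpha[0] - eta), 0, np.where(u < expit(alpha[1] - eta), 1, 2)
        ).astype(float)
        return y, X, z, gi, beta, sigma, alpha
    y = (rng.random(G * n_t) < expit(eta)).astype(float)
    return y, X, z, gi, beta, sigma, None


def brute_force_loglik(y, X, z, gi, beta, sigma, aux=None, ordinal=False):
    """2-D quadrature over each cluster's random effect, independent of AGQ."""
    si = np.linalg.inv(sigma)
    det = np.linalg.det(sigma)
    total = 0.0
    for g in np.unique(gi):
        m = gi == g
        yy, XX, zz = y[m], X[m], z[m]

        def integrand(b1, b0):
            e = XX @ beta + b0 + b1 * zz
            if ordinal:
                alpha = np.concatenate([aux, [np.inf]])
                hi = np.where(yy <= len(aux) - 1, expit(alpha[yy.astype(int)] - e), 1.0)
                lo = np.where(yy >= 1, expit(alpha[yy.astype(int) - 1] - e), 0.0)
                ll = np.log(hi - lo).sum()
            else:
                ll = np.sum(yy * e - np.logaddexp(0, e))
            quad = si[0, 0] * b0**2 + 2 * si[0, 1] * b0 * b1 + si[1, 1] * b1**2
            return np.exp(ll - 0.5 * quad) / (2 * np.pi * np.sqrt(det))

        val, _ = integrate.dblquad(integrand, -9, 9, -9, 9, epsabs=1e-13, epsrel=1e-11)
        total += np.log(val)
    return total


class TestQuadrature:
    def test_agq_matches_brute_force_binary(self):
        y, X, z, gi, beta, sigma, _ = toy_data()
        ll, _ = marginal_loglik(y, X, z, gi, beta, sigma, n_quad=21)
        bf = brute_force_loglik(y, X, z, gi, beta, sigma)
        assert abs(ll - bf) < 1e-6

    def test_agq_matches_brute_force_ordinal(self):
        y, X, z, gi, beta, sigma, alpha = toy_data(ordinal=True)
        aux = np.array([alpha[0], np.log(alpha[1] - alpha[0])])
        ll, _ = marginal_loglik(
            y, X, z, gi, beta, sigma, n_quad=21, family="ordinal", aux=aux
        )
        bf = brute_force_loglik(y, X, z, gi, beta, sigma, aux=alpha, ordinal=True)
        assert abs(ll - bf) < 1e-6

    def test_node_count_converges_monotonically(self):
        """AGQ error against the brute-force integral shrinks with node count."""
        y, X, z, gi, beta, sigma, _ = toy_data(G=5, n_t=6, seed=3)
        bf = brute_force_loglik(y, X, z, gi, beta, sigma)
        errors = []
        for q in (1, 3, 5, 9, 15):
            ll, _ = marginal_loglik(y, X, z, gi, beta, sigma, n_quad=q)
            errors.append(abs(ll - bf))
        assert errors[-1] < 1e-8
        assert all(e2 <= e1 + 1e-12 for e1, e2 in zip(errors, errors[1:]))

    def test_analytic_score_matches_finite_differences(self):
        y, X, z, gi, beta, sigma, _ = toy_data(seed=4)
        prob = AGQProblem(y, X, z, gi, BinaryFamily, n_quad=15)
        theta = np.concatenate([beta, theta_from_sigma(sigma)])
        res = prob.eval(theta)
        for j in range(theta.size):
            e = np.zeros(theta.size)
            e[j] = 1e-6
            num = (
                prob.eval(theta + e, want_grad=False).nll
                - prob.eval(theta - e, want_grad=False).nll
            ) / 2e-6
            assert abs(res.grad[j] - num) < 1e-5


class TestMixedLogit:
    def test_zero_variance_data_reproduces_plain_logistic(self):
        statsmodels = pytest.importorskip("statsmodels.api")
        cfg = pv.SimConfig(
            n_participants=50, followup_days=200, seed=42,
            re_covariance=ZERO, re_covariance_cas=ZERO, withdrawal_hazard_per_day=0.0,
        )
        truth, _ = simulate_truth(cfg)
        truth = truth.rename(columns={"latent_dose_taken": "dose_day"})
        spec = MixedModelSpec(n_quad=5)
        fit = fit_mixed_logit(truth, outcome="dose_day", spec=spec)
        X, _, _ = build_design(truth, spec)
        ref = statsmodels.Logit(truth["dose_day"].to_numpy(float), X).fit(
            disp=0, method="newton", tol=1e-12
        )
        assert np.abs(fit.beta - ref.params).max() < 1e-4
        assert max(fit.re_covariance[0, 0], fit.re_covariance[1, 1]) < 1e-2
        assert fit.boundary

    def test_missing_outcomes_dropped_and_counted(self, small_panel):
        fit = fit_mixed_logit(
            small_panel, outcome="cas_day",
            spec=MixedModelSpec(knots=(-60.0, 0.0, 60.0), n_quad=3),
        )
        assert fit.n_obs + fit.n_dropped == len(small_panel)

    def test_time_origin_shift_changes_only_intercept(self):
        """z-statistics of spline terms are invariant to a common time shift."""
        cfg = pv.SimConfig(n_participants=25, followup_days=150, seed=8,
                           withdrawal_hazard_per_day=0.0)
        truth, _ = simulate_truth(cfg)
        truth = truth.rename(columns={"latent_dose_taken": "dose_day"})
        shift = 37.0
        spec0 = MixedModelSpec(knots=(-126.0, -24.0, 64.0, 184.0), n_quad=3)
        spec1 = MixedModelSpec(
            knots=tuple(k + shift for k in spec0.knots), n_quad=3
        )
        fit0 = fit_mixed_logit(truth, outcome="dose_day", spec=spec0)
        shifted = truth.copy()
        shifted["t"] = shifted["t"] + shift
        fit1 = fit_mixed_logit(shifted, outcome="dose_day", spec=spec1)
        z0 = (fit0.beta / fit0.se_robust)[1:4]
        z1 = (fit1.beta / fit1.se_robust)[1:4]
        np.testing.assert_allclose(z0, z1, rtol=1e-2)
        # nonlinear spline coefficients themselves are shift-invariant
        np.testing.assert_allclose(fit0.beta[2:4], fit1.beta[2:4], rtol=1e-2)

    def test_pandemic_or_recovery_single_cohort(self):
        cfg = pv.SimConfig(n_participants=60, followup_days=270, seed=11,
                           withdrawal_hazard_per_day=0.0)
        truth, _ = simulate_truth(cfg)
        truth = truth.rename(columns={"latent_dose_taken": "dose_day"})
        fit = fit_mixed_logit(truth, outcome="dose_day", spec=MixedModelSpec(n_quad=5))
        i = fit.terms.index("pandemic")
        lo = fit.beta[i] - 1.96 * fit.se_robust[i]
        hi = fit.beta[i] + 1.96 * fit.se_robust[i]
        assert lo <= np.log(0.44) <= hi
        # variance components land in the right region
        assert 1.0 < fit.re_covariance[0, 0] < 12.0
        assert fit.re_covariance[0, 1] < 0.5


class TestMixedOrdinal:
    def test_two_category_ordinal_equals_binary_logit(self):
        cfg = pv.SimConfig(n_participants=30, followup_days=120, seed=9,
                           withdrawal_hazard_per_day=0.0)
        truth, _ = simulate_truth(cfg)
        truth = truth.rename(columns={"latent_cas_day": "cas_day"})
        spec = MixedModelSpec(knots=pv.SimConfig().cas_knots, n_quad=5)
        fb = fit_mixed_logit(truth, outcome="cas_day", spec=spec)
        fo = fit_mixed_ologit(truth, outcome="cas_day", spec=spec)
        np.testing.assert_allclose(fo.beta, fb.beta[1:], atol=1e-4)
        np.testing.assert_allclose(fo.thresholds, [-fb.beta[0]], atol=1e-4)

    def test_thresholds_strictly_increasing(self):
        cfg = pv.SimConfig(n_participants=40, followup_days=150, seed=13,
                           withdrawal_hazard_per_day=0.0)
        truth, _ = simulate_truth(cfg)
        truth = truth.rename(columns={"latent_episode_count": "episode_count"})
        fit = fit_mixed_ologit(
            truth, outcome="episode_count",
            spec=MixedModelSpec(knots=pv.SimConfig().cas_knots, n_quad=3),
        )
        assert (np.diff(fit.thresholds) > 0).all()

    def test_single_category_outcome_rejected(self, small_panel):
        flat = small_panel.copy()
        flat["episode_count"] = 0.0
        with pytest.raises(ValueError, match="2 observed categories"):
            fit_mixed_ologit(flat)


class TestJointTest:
    def test_identical_models_give_zero_chi2(self):
        cfg = pv.SimConfig(n_participants=30, followup_days=150, seed=15,
                           withdrawal_hazard_per_day=0.0)
        truth, _ = simulate_truth(cfg)
        truth = truth.rename(columns={"latent_dose_taken": "dose_day"})
        full = fit_mixed_logit(
            truth, outcome="dose_day",
            spec=MixedModelSpec(spline_by_pandemic=True, n_quad=3),
        )
        reduced = fit_mixed_logit(
            truth, outcome="dose_day", spec=MixedModelSpec(n_quad=3)
        )
        chi2, df, p = joint_interaction_test(full, reduced)
        assert df == 3  # three spline x pandemic terms for a 4-knot model
        assert chi2 >= 0 and 0 <= p <= 1
        degenerate = full
        chi2_same, _, p_same = joint_interaction_test(degenerate)
        assert chi2_same == pytest.approx(chi2)

    def test_non_nested_models_rejected(self):
        cfg = pv.SimConfig(n_participants=25, followup_days=220, seed=16,
                           withdrawal_hazard_per_day=0.0)
        truth, _ = simulate_truth(cfg)
        truth = truth.rename(columns={"latent_dose_taken": "dose_day"})
        from prevently.rcs import quantile_knots

        knots = quantile_knots(truth["t"].to_numpy(), 4).knots
        full = fit_mixed_logit(
            truth, outcome="dose_day",
            spec=MixedModelSpec(knots=knots, spline_by_pandemic=True, n_quad=1),
        )
        t_lo, t_hi = truth["t"].min(), truth["t"].max()
        inner = (t_lo + 5.0, (t_lo + t_hi) / 2.0, t_hi - 5.0)
        other = fit_mixed_logit(
            truth, outcome="dose_day", spec=MixedModelSpec(knots=inner, n_quad=1)
        )
        with pytest.raises(ValueError, match="not nested"):
            joint_interaction_test(full, other)


class TestLaggedAssociation:
    def test_lag_alignment_pairs_previous_day_dose(self):
        # doses on even days; CAS only where yesterday had a dose
        from tests.test_adherence import panel_from_pattern

        panel = panel_from_pattern("10" * 10, [])
        df = panel.copy()
        lagged = df.groupby("participant_id")["dose_day"].shift(1)
        aligned = pd.DataFrame({"dose_lag": lagged, "dose": df["dose_day"]}).dropna()
        assert (aligned["dose_lag"].to_numpy()[1:] == df["dose_day"].to_numpy()[1:-1]).all()

    def test_recovers_null_and_positive_lag_effects(self):
        base = dict(n_participants=50, followup_days=220, seed=77,
                    withdrawal_hazard_per_day=0.0)
        for true_or in (1.0, 1.93):
            fe = pv.FixedEffects(lag_log_or_prep_to_cas=np.log(true_or))
            cfg = pv.SimConfig(fixed_effects=fe, **base)
            truth, _ = simulate_truth(cfg)
            truth = truth.rename(
                columns={"latent_dose_taken": "dose_day", "latent_cas_day": "cas_day"}
            )
            fit = fit_lagged_association(truth, lag_days=1, n_quad=3)
            i = fit.terms.index("dose_lag1")
            lo = fit.beta[i] - 1.96 * fit.se_robust[i]
            hi = fit.beta[i] + 1.96 * fit.se_robust[i]
            assert lo <= np.log(true_or) <= hi


class TestMarginalPrediction:
    def test_zero_variance_reduces_to_inverse_logit(self):
        eta = np.array([-1.0, 0.0, 2.0])
        out = marginal_probability(eta, np.zeros(3), None)
        np.testing.assert_allclose(out, expit(eta))

    def test_quadrature_matches_monte_carlo(self):
        sigma = np.array([[1.5, -0.4], [-0.4, 1.0]])
        rng = np.random.default_rng(0)
        b = rng.multivariate_normal([0, 0], sigma, 200_000)
        eta = np.array([0.3, -0.5, 1.2])
        z = np.array([0.0, 1.0, 1.0])
        mc = np.array([expit(eta[i] + b[:, 0] + b[:, 1] * z[i]).mean() for i in range(3)])
        gq = marginal_probability(eta, z, sigma, n_quad=40)
        assert np.abs(mc - gq).max() < 1e-3

    def test_curve_is_valid_and_warns_on_extrapolation(self):
        cfg = pv.SimConfig(n_participants=25, followup_days=150, seed=30,
                           withdrawal_hazard_per_day=0.0)
        truth, _ = simulate_truth(cfg)
        truth = truth.rename(columns={"latent_dose_taken": "dose_day"})
        fit = fit_mixed_logit(truth, outcome="dose_day", spec=MixedModelSpec(n_quad=3))
        grid = np.arange(truth["t"].min(), truth["t"].max(), 5.0)
        probs = predict_marginal_prob(fit, grid)
        assert ((probs > 0) & (probs < 1)).all()
        assert np.abs(np.diff(probs)).max() < 0.2  # no discontinuity except the step
        with pytest.warns(UserWarning, match="extrapolating"):
            predict_marginal_prob(fit, [truth["t"].max() + 500])
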