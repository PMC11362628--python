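"""Gaussian-process model: kernel, likelihood, conditioning, fitting, PEx
probabilities — each checked against an independent oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from conftest import make_encounter, make_patient, make_registry
from pexaudit.gp import (
    ModelParams, ParameterError, conditional_prediction, design_matrix,
    fit_model, ibm_kernel, log_likelihood, marginal_covariance, pex_probability,
)
from pexaudit.simulate import SimulationConfig, default_true_params, generate_registry


def simple_params(G=None, sigma_w2=0.0, sigma_e2=1.0, beta=None):
    return ModelParams(
        beta=np.zeros(6) if beta is None else np.asarray(beta, float),
        G=np.zeros((2, 2)) if G is None else np.asarray(G, float),
        sigma_w2=sigma_w2, sigma_e2=sigma_e2)


PATIENT = pd.Series({**make_patient("P1")})


def history_frame(times, fevs):
    rows = [make_encounter("P1", float(t), float(f)) for t, f in zip(times, fevs)]
    return pd.DataFrame(rows)


class TestIbmKernel:
    def test_unit_time_value(self):
        assert ibm_kernel(1.0, 1.0) == pytest.approx(1.0 / 3.0)

    def test_zero_time_gives_zero(self):
        assert ibm_kernel(0.0, 5.0) == 0.0

    def test_closed_form_example(self):
        assert ibm_kernel(1.0, 2.0) == pytest.approx(5.0 / 6.0)

    @pytest.mark.parametrize("s,t", [(0.5, 0.5), (1.0, 2.0), (3.0, 0.7), (2.5, 2.5)])
    def test_matches_numerical_double_integral(self, s, t):
        # cov(W(s), W(t)) = int_0^s int_0^t min(u, v) dv du
        val, _ = integrate.dblquad(lambda v, u: min(u, v), 0, s, 0, t,
                                   epsabs=1e-10)
        assert ibm_kernel(s, t) == pytest.approx(val, abs=1e-6)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            ibm_kernel(-1.0, 2.0)

    def test_symmetry_vectorized(self):
        s = np.array([0.0, 1.0, 4.0])
        np.testing.assert_allclose(ibm_kernel(s[:, None], s[None, :], 2.0),
                                   ibm_kernel(s[None, :], s[:, None], 2.0))


class TestMarginalCovariance:
    def test_single_time_zero_G(self):
        V = marginal_covariance(np.array([0.0]), simple_params(sigma_e2=2.5))
        np.testing.assert_allclose(V, [[2.5]])

    def test_psd_for_random_params(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            A = rng.standard_normal((2, 2))
            params = simple_params(G=A @ A.T, sigma_w2=float(rng.random()),
                                   sigma_e2=float(rng.random()) + 0.1)
            times = np.sort(rng.uniform(0, 100, size=6))
            eig = np.linalg.eigvalsh(marginal_covariance(times, params))
            assert eig.min() >= -1e-8

    def test_matches_simulation_covariance(self):
        # oracle shared with the generator: empirical covariance of many
        # simulated trajectories approaches Z G Z' + sw2 K + se2 I
        from pexaudit.simulate import simulate_fev1
        params = ModelParams(beta=np.array([90.0, 0, 0, 0, 0, 0]),
                             G=np.array([[9.0, 0.01], [0.01, 1e-4]]),
                             sigma_w2=1e-4, sigma_e2=4.0)
        times = np.array([0.0, 30.0, 90.0, 180.0])
        rng = np.random.default_rng(42)
        sims = np.array([
            simulate_fev1(PATIENT, times, params, rng)[0] for _ in range(10000)])
        emp = np.cov(sims.T)
        expected = marginal_covariance(times, params)
        # MC error on a covariance entry ~ |V| * sqrt(2/n); allow 5 sigma
        tol = 5 * np.sqrt(2.0 / 10000) * np.abs(expected).max()
        np.testing.assert_allclose(emp, expected, atol=tol)

    def test_non_psd_G_rejected(self):
        with pytest.raises(ParameterError):
            simple_params(G=[[1.0, 2.0], [2.0, 1.0]])


class TestLogLikelihood:
    def test_standard_normal_at_zero(self):
        reg = make_registry([make_patient("P1")], [make_encounter("P1", 0.0, 1e-12)])
        params = simple_params()  # beta 0 -> residual ~0, V = [1]
        assert log_likelihood(reg, params) == pytest.approx(-0.5 * np.log(2 * np.pi))

    def test_matches_dense_block_oracle(self):
        patients = [make_patient(f"P{i}") for i in range(3)]
        encounters = []
        rng = np.random.default_rng(5)
        for i in range(3):
            for t in np.sort(rng.choice(200, size=i + 2, replace=False)):
                encounters.append(make_encounter(f"P{i}", float(t), float(80 + rng.random() * 20)))
        reg = make_registry(patients, encounters)
        params = ModelParams(beta=np.array([85.0, 0.2, 0, 0, 0, 0]),
                             G=np.array([[16.0, 0], [0, 1e-5]]),
                             sigma_w2=1e-5, sigma_e2=4.0)
        # independent oracle: one dense multivariate normal over all patients
        blocks, resid = [], []
        for pid in ("P0", "P1", "P2"):
            grp = reg.patient_encounters(pid)
            X = design_matrix(pd.Series(make_patient(pid)), grp, params.terms)
            blocks.append(marginal_covariance(grp["t"].to_numpy(float), params))
            resid.append(grp["fev1_pp"].to_numpy(float) - X @ params.beta)
        from scipy.linalg import block_diag
        dense = stats.multivariate_normal(
            mean=np.zeros(sum(len(r) for r in resid)),
            cov=block_diag(*blocks)).logpdf(np.concatenate(resid))
        assert log_likelihood(reg, params) == pytest.approx(float(dense), rel=1e-10)

    def test_decreases_with_residual_magnitude(self):
        params = simple_params(sigma_e2=4.0, beta=[90, 0, 0, 0, 0, 0])
        lls = []
        for shift in (0.0, 5.0, 10.0):
            reg = make_registry([make_patient("P1")],
                                [make_encounter("P1", 0.0, 90.0 + shift)])
            lls.append(log_likelihood(reg, params))
        assert lls[0] > lls[1] > lls[2]


class TestConditionalPrediction:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_partitioned_gaussian_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_obs = int(rng.integers(1, 5))
        n_fut = int(rng.integers(1, 7 - n_obs))
        times = np.sort(rng.uniform(0, 500, size=n_obs + n_fut))
        t_obs, t_fut = times[:n_obs], times[n_obs:]
        params = ModelParams(beta=np.array([90.0, -0.5, 0, 0, 0, 0]),
                             G=np.array([[25.0, 0.002], [0.002, 3e-5]]),
                             sigma_w2=1e-5, sigma_e2=float(rng.random() * 3 + 0.5))
        hist = history_frame(t_obs, 80 + rng.standard_normal(n_obs) * 5)
        pred = conditional_prediction(hist, t_fut, params, PATIENT)

        X_obs = design_matrix(PATIENT, hist, params.terms)
        X_fut = np.repeat(design_matrix(PATIENT, hist.iloc[[-1]], params.terms),
                          n_fut, axis=0)
        V = marginal_covariance(np.concatenate([t_obs, t_fut]), params)
        Vhh, Vff = V[:n_obs, :n_obs], V[n_obs:, n_obs:]
        Vfh = V[n_obs:, :n_obs]
        y = hist["fev1_pp"].to_numpy(float)
        m = X_fut @ params.beta + Vfh @ np.linalg.inv(Vhh) @ (y - X_obs @ params.beta)
        c = Vff - Vfh @ np.linalg.inv(Vhh) @ Vfh.T
        assert np.linalg.norm(pred.mean - m) < 1e-8
        assert np.linalg.norm(pred.covariance - c) < 1e-8

    def test_empty_history_returns_prior(self):
        params = simple_params(G=[[4.0, 0], [0, 1e-6]], sigma_e2=1.0,
                               beta=[90, 0, 0, 0, 0, 0])
        hist = history_frame([], [])
        pred = conditional_prediction(hist, np.array([10.0, 20.0]), params, PATIENT)
        np.testing.assert_allclose(pred.mean, [90.0, 90.0])
        np.testing.assert_allclose(pred.covariance,
                                   marginal_covariance(np.array([10.0, 20.0]), params))

    def test_interpolation_limit_small_noise(self):
        # as sigma_e2 -> 0, predicting at (just after) an observed time
        # reproduces the observation with vanishing variance
        params = ModelParams(beta=np.array([90.0, 0, 0, 0, 0, 0]),
                             G=np.array([[25.0, 0], [0, 1e-5]]),
                             sigma_w2=1e-5, sigma_e2=1e-10)
        hist = history_frame([0.0, 50.0], [95.0, 85.0])
        pred = conditional_prediction(hist, np.array([50.0 + 1e-6]), params, PATIENT)
        assert pred.mean[0] == pytest.approx(85.0, abs=1e-3)
        assert pred.covariance[0, 0] < 1e-4


class TestPexProbability:
    params = ModelParams(beta=np.array([90.0, 0, 0, 0, 0, 0]),
                         G=np.array([[25.0, 0], [0, 3e-5]]),
                         sigma_w2=1e-5, sigma_e2=4.0)
    hist = history_frame([0.0, 60.0, 120.0], [88.0, 86.0, 84.0])

    def test_single_point_grid_matches_phi(self):
        n = 40000
        p_mc = pex_probability(self.hist, 120.0, 90.0, 30.0, self.params, PATIENT,
                               n_samples=n, grid_step_days=30.0, seed=11)
        pred = conditional_prediction(self.hist, np.array([150.0]), self.params, PATIENT)
        p_true = float(stats.norm.cdf(
            (80.0 - pred.mean[0]) / np.sqrt(pred.covariance[0, 0])))
        mc_se = np.sqrt(p_true * (1 - p_true) / n)
        assert abs(p_mc - p_true) <= 3 * mc_se

    def test_far_tail_probability_negligible(self):
        # predictive mean ~84, threshold 50 - 10 = 40: ~40 points below
        pred_far = pex_probability(self.hist, 120.0, 50.0, 30.0, self.params,
                                   PATIENT, n_samples=2000, grid_step_days=30.0, seed=1)
        assert pred_far < 0.001

    def test_monotone_in_horizon_under_common_seed(self):
        for seed in range(5):
            ps = [pex_probability(self.hist, 120.0, 90.0, h, self.params, PATIENT,
                                  n_samples=500, seed=seed)
                  for h in (91.3125, 182.625, 365.25)]
            assert ps[0] <= ps[1] <= ps[2]

    def test_undefined_baseline_rejected(self):
        with pytest.raises(ValueError):
            pex_probability(self.hist, 120.0, float("nan"), 30.0, self.params, PATIENT)

    def test_union_bound_dominates_mc(self):
        p_mc = pex_probability(self.hist, 120.0, 88.0, 182.625, self.params,
                               PATIENT, n_samples=4000, seed=3)
        p_ub = pex_probability(self.hist, 120.0, 88.0, 182.625, self.params,
                               PATIENT, method="union_bound")
        assert p_ub >= p_mc - 0.03


class TestFit:
    def test_recovery_and_optimum_dominates_truth(self):
        cfg = SimulationConfig(n_patients=80, seed=21, followup_years_mean=4.0)
        reg = generate_registry(cfg)
        fit = fit_model(reg)
        true = cfg.true_params
        assert fit.converged
        assert fit.params.sigma_e2 == pytest.approx(true.sigma_e2, rel=0.15)
        # the fitted optimum must dominate the generating parameters
        ll_true = log_likelihood(reg, ModelParams(
            beta=fit.params.beta, G=true.G, sigma_w2=true.sigma_w2,
            sigma_e2=true.sigma_e2))
        assert fit.log_likelihood >= ll_true - 1e-6
        # each beta within 3 GLS standard errors of the truth
        assert np.all(np.abs(fit.params.beta - true.beta) <= 3 * fit.beta_se)

    def test_multistart_stability(self):
        cfg = SimulationConfig(n_patients=50, seed=22, followup_years_mean=3.0)
        reg = generate_registry(cfg)
        fit1 = fit_model(reg)
        perturbed = ModelParams(
            beta=fit1.params.beta,
            G=fit1.params.G * 2.5 + np.diag([1.0, 1e-8]),
            sigma_w2=fit1.params.sigma_w2 * 5 + 1e-9,
            sigma_e2=fit1.params.sigma_e2 * 0.4)
        fit2 = fit_model(reg, init=perturbed)
        assert fit2.log_likelihood == pytest.approx(fit1.log_likelihood, abs=1e-4)

    def test_reml_close_to_ml_at_scale(self):
        cfg = SimulationConfig(n_patients=50, seed=23, followup_years_mean=3.0)
        reg = generate_registry(cfg)
        ml = fit_model(reg)
        reml = fit_model(reg, reml=True)
        assert reml.params.sigma_e2 == pytest.approx(ml.params.sigma_e2, rel=0.1)
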