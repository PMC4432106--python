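"""FOCE-I estimator: exact Gaussian oracles, conditional modes,
recovery, and the covariance step."""

import math

import numpy as np
import pytest
from scipy.stats import multivariate_normal

import toxkinsim as tk
from toxkinsim.errors import InputError
from toxkinsim.nlme import (
    CustomStructural,
    FoceiEngine,
    PKStructural,
    SubjectData,
    build_subjects,
    conditional_etas,
    covariance_step,
    fit_population,
    focei_objective,
    _central_hessian,
)

SPEC_A = tk.ModelSpec(tk.ModelId.ONE_CMT)
PARAMS_A = {"KA": 13.46, "V": 49.4, "CL": 2.72}


def linear_engine(y, subj, a=2.0, b=1.5):
    """Toy model linear in eta with additive error (Gaussian algebra
    is exact, so the Laplace objective must equal the true -2LL)."""
    subj = np.asarray(subj)

    def predict(_theta, etas):
        return a + b * etas[subj, 0]

    st = CustomStructural(predict, np.asarray(y, float), subj, d=1)
    return FoceiEngine(st, error_model="additive", inner_gtol=1e-12)


class TestObjectiveOracles:
    def test_equals_exact_gaussian_marginal_one_obs(self):
        a, b, om, sig = 2.0, 1.5, 0.7, 0.3
        eng = linear_engine([2.9], [0], a, b)
        ofv = eng.ofv(None, np.array([om]), sig)
        vtot = b * b * om * om + sig * sig
        exact = math.log(2 * math.pi * vtot) + (2.9 - a) ** 2 / vtot
        assert ofv == pytest.approx(exact, abs=1e-8)

    def test_equals_exact_gaussian_marginal_multi_subject(self):
        a, b, om, sig = 1.0, 0.8, 0.5, 0.2
        y = np.array([1.4, 0.7, 1.1, 0.9, 1.6])
        subj = np.array([0, 0, 0, 1, 1])
        eng = linear_engine(y, subj, a, b)
        ofv = eng.ofv(None, np.array([om]), sig)
        exact = 0.0
        for s, n in ((0, 3), (1, 2)):
            ys = y[subj == s]
            cov = b * b * om * om * np.ones((n, n)) + sig * sig * np.eye(n)
            exact += -2 * multivariate_normal.logpdf(ys, np.full(n, a), cov)
        assert ofv == pytest.approx(exact, abs=1e-7)

    def test_duplicating_every_subject_doubles_the_objective(self):
        y = np.array([1.4, 0.7, 0.9])
        subj = np.array([0, 0, 1])
        eng1 = linear_engine(y, subj)
        eng2 = linear_engine(np.concatenate([y, y]),
                             np.concatenate([subj, subj + 2]))
        om, sig = np.array([0.6]), 0.25
        assert eng2.ofv(None, om, sig) == pytest.approx(
            2 * eng1.ofv(None, om, sig), rel=1e-10)

    def test_focei_objective_from_dataset(self, week_dataset):
        ofv = focei_objective(week_dataset, PARAMS_A,
                              {"KA": 0.25, "V": 0.0256, "CL": 0.04}, 0.15,
                              SPEC_A)
        assert np.isfinite(ofv)


class TestConditionalEtas:
    def test_shrinkage_to_zero_as_omega_vanishes(self):
        sub = SubjectData(id=1,
                          obs_times=np.array([0.5, 2.0, 8.0]),
                          y=np.array([0.5, 0.45, 0.3]),
                          dose_times=np.array([0.0]),
                          dose_amts=np.array([30.0]))
        eta, H = conditional_etas(sub, PARAMS_A,
                                  {"KA": 1e-8, "V": 1e-8, "CL": 1e-8},
                                  0.15, SPEC_A)
        assert np.abs(eta).max() < 1e-4
        assert H.shape == (3, 3)

    def test_recovers_simulating_eta_from_rich_noise_free_data(self):
        rng = np.random.default_rng(5)
        eta_true = np.array([0.3, -0.1, 0.15])
        values = {k: PARAMS_A[k] * math.exp(e)
                  for k, e in zip(("KA", "V", "CL"), eta_true)}
        t = np.linspace(0.2, 24.0, 30)
        c = tk.predict_concentration(SPEC_A, values,
                                     tk.DoseRegimen(30.0, 1), t)
        sub = SubjectData(id=1, obs_times=t, y=c,
                          dose_times=np.array([0.0]),
                          dose_amts=np.array([30.0]))
        eta, _ = conditional_etas(sub, PARAMS_A,
                                  {"KA": 1.0, "V": 1.0, "CL": 1.0},
                                  0.01, SPEC_A)
        # small residual shrinkage toward zero remains under the finite
        # N(0, 1) prior even with near-noise-free data
        np.testing.assert_allclose(eta, eta_true, atol=6e-3)

    def test_subject_without_observations_rejected(self):
        sub = SubjectData(id=1, obs_times=np.array([]), y=np.array([]),
                          dose_times=np.array([0.0]), dose_amts=np.array([30.0]))
        with pytest.raises(InputError):
            conditional_etas(sub, PARAMS_A, {"CL": 0.04}, 0.15, SPEC_A)


class TestBuildSubjects:
    def test_vehicle_and_empty_subjects_dropped(self, week_dataset):
        filtered = tk.apply_bql_filter(week_dataset, 1e-6)  # removes vehicle obs
        subs = build_subjects(filtered.estimator_view())
        # 3 active dose groups x (4 toxicity + 3 satellite)
        assert len(subs) == 21
        assert all(s.dose_amts.max() > 0 for s in subs)

    def test_analytic_jacobian_matches_finite_differences(self, week_dataset):
        subs = build_subjects(week_dataset.estimator_view())
        st = PKStructural(SPEC_A, subs, ("KA", "V", "CL"))
        st.set_theta(PARAMS_A)
        rng = np.random.default_rng(0)
        etas = rng.normal(0, 0.3, (st.n_subjects, 3))
        f, J = st.predict_with_jac(etas)
        h = 1e-7
        for k in range(3):
            e = etas.copy()
            e[:, k] += h
            fd = (st.predict(e) - f) / h
            np.testing.assert_allclose(J[:, k], fd, rtol=2e-4, atol=1e-10)


class TestFitPopulation:
    def test_noise_free_recovery_of_simulating_values(self):
        # sigma ~ 0, BSV = 0, rich sampling: typical values recovered
        # to well under 0.1 %
        pop0 = tk.PopulationParameters(theta=dict(PARAMS_A), bsv_cv={},
                                       sigma_prop=0.0)
        design = tk.build_cohort_design(
            "1_WEEK",
            {"times_within_day": (0.05, 0.1, 0.2, 0.4, 0.7, 1.0, 1.5, 2.5,
                                  4.0, 6.0, 8.0, 12.0, 18.0, 24.0)})
        ds = tk.simulate_trial(design, SPEC_A, pop0, 1)
        init = tk.PopulationParameters(
            theta={k: v * 1.1 for k, v in PARAMS_A.items()},
            bsv_cv={"KA": 2.0, "V": 2.0, "CL": 2.0}, sigma_prop=0.02)
        fit = fit_population(ds, SPEC_A, init, do_covariance=False)
        assert fit.converged
        for k, v in PARAMS_A.items():
            assert abs(fit.theta[k] / v - 1) < 1e-3, k
        # exposures derived from the recovered parameters reproduce the
        # true exposures to comparable accuracy
        reg = tk.DoseRegimen(dose=30.0, n_doses=7)
        got = tk.exposure_from_params(SPEC_A, fit.theta, reg, 7,
                                      measures=("auc24", "cmax24"))
        ref = tk.exposure_from_params(SPEC_A, PARAMS_A, reg, 7,
                                      measures=("auc24", "cmax24"))
        assert got.auc24 == pytest.approx(ref.auc24, rel=2e-3)
        assert got.cmax24 == pytest.approx(ref.cmax24, rel=2e-3)

    def test_estimation_uses_only_the_estimator_view(self, monkeypatch,
                                                     week_dataset):
        # fit_population must consume TKDataset.estimator_view(), which
        # carries no truth columns
        seen = {}
        orig = tk.TKDataset.estimator_view

        def spy(self):
            df = orig(self)
            seen["columns"] = list(df.columns)
            return df

        monkeypatch.setattr(tk.TKDataset, "estimator_view", spy)
        init = tk.PopulationParameters(theta=dict(PARAMS_A),
                                       bsv_cv={"KA": 50.0, "V": 16.0, "CL": 20.0},
                                       sigma_prop=0.15)
        fit = fit_population(week_dataset, SPEC_A, init, do_covariance=False,
                             outer_maxiter=2, max_restarts=0)
        assert "TRUE_DV" not in seen["columns"]

    def test_far_initialization_never_claims_spurious_covariance(self,
                                                                 week_dataset):
        init = tk.PopulationParameters(
            theta={k: v * 100 for k, v in PARAMS_A.items()},
            bsv_cv={"KA": 50.0, "V": 16.0, "CL": 20.0}, sigma_prop=0.15)
        fit = fit_population(week_dataset, SPEC_A, init, outer_maxiter=60,
                             max_restarts=1)
        # contract: either a proper optimum or converged=False; a
        # covariance success implies a converged fit
        assert fit.covariance_ok <= fit.converged


class TestCovarianceStep:
    def test_standard_errors_match_quadratic_oracle(self):
        # f(x) = (x-c)' A (x-c): Hessian of f/2 is A, SEs = sqrt(diag(A^-1))
        A = np.array([[4.0, 1.0, 0.0], [1.0, 3.0, 0.5], [0.0, 0.5, 2.0]])
        c = np.array([0.3, -0.2, 1.0])

        def f(x):
            d = x - c
            return float(d @ A @ d)

        H = 0.5 * _central_hessian(f, c.copy())
        np.testing.assert_allclose(H, A, atol=1e-5)
        se = np.sqrt(np.diag(np.linalg.inv(H)))
        np.testing.assert_allclose(se, np.sqrt(np.diag(np.linalg.inv(A))),
                                   rtol=1e-4)

    def test_non_stationary_point_detected_as_failure(self, week_dataset):
        # covariance step at a saddle/non-optimum must not report success
        init = tk.PopulationParameters(theta=dict(PARAMS_A),
                                       bsv_cv={"KA": 50.0, "V": 16.0, "CL": 20.0},
                                       sigma_prop=0.15)
        fit = fit_population(week_dataset, SPEC_A, init, do_covariance=False,
                             outer_maxiter=300)
        assert fit.converged
        # corrupt the solution: far from stationary
        fit.theta = {k: v * 3 for k, v in fit.theta.items()}
        out = covariance_step(fit, week_dataset, SPEC_A)
        assert not out.covariance_ok
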