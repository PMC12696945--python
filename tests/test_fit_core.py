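"""The pooled RS algorithm: deviance, PWLS solves, backfitting, full fits."""

import numpy as np
import pandas as pd
import pytest

from fedgamlss import (
    Control,
    ModelSpec,
    RankDeficiencyError,
    SpecificationError,
    backfit_cycle,
    fit_pooled,
    get_family,
    global_deviance,
    inner_iteration,
    predict_parameters,
    pwls_solve,
)
from fedgamlss.model import build_param_design
from fedgamlss.smoothers import bspline_basis, default_knots, difference_penalty
from fedgamlss.synthetic import growth_truth_theta


class TestGlobalDeviance:
    def test_single_observation_closed_form(self):
        fam = get_family("NO")
        th = {"mu": np.array([2.0]), "sigma": np.array([1.0])}
        assert global_deviance(fam, np.array([2.0]), th) == pytest.approx(
            np.log(2 * np.pi), abs=1e-9)

    def test_three_point_closed_form(self):
        fam = get_family("NO")
        y = np.array([0.0, 1.0, 2.0])
        th = {"mu": np.full(3, 1.0), "sigma": np.full(3, 1.0)}
        assert global_deviance(fam, y, th) == pytest.approx(
            3 * np.log(2 * np.pi) + 2.0, abs=1e-9)

    def test_additive_over_partitions(self):
        fam = get_family("BCPE")
        rng = np.random.default_rng(0)
        y = rng.uniform(90, 150, 40)
        th = {"mu": np.full(40, 120.0), "sigma": np.full(40, 0.05),
              "nu": np.full(40, 1.0), "tau": np.full(40, 2.0)}
        whole = global_deviance(fam, y, th)
        parts = sum(global_deviance(fam, y[s], {k: v[s] for k, v in th.items()})
                    for s in (slice(0, 13), slice(13, 40)))
        assert whole == pytest.approx(parts, rel=1e-12)


class TestPwlsSolve:
    def test_identity_system(self):
        np.testing.assert_allclose(pwls_solve(np.eye(2), np.array([1.0, 2.0])),
                                   [1.0, 2.0])

    def test_random_spd_vs_brute_force(self):
        rng = np.random.default_rng(4)
        A = rng.normal(size=(12, 5))
        W = np.diag(rng.uniform(0.5, 2.0, 12))
        z = rng.normal(size=12)
        G = difference_penalty(5, 2)
        ctwc, ctwz = A.T @ W @ A, A.T @ W @ z
        oracle = np.linalg.inv(ctwc + G) @ ctwz      # brute-force normal equations
        np.testing.assert_allclose(pwls_solve(ctwc, ctwz, penalty=G), oracle,
                                   atol=1e-10)

    def test_infinite_penalty_limit_is_best_fit_line(self):
        # q = 4, order-2 penalty: lambda -> inf projects onto {linear sequences}
        rng = np.random.default_rng(8)
        z = rng.normal(size=4)
        G = difference_penalty(4, 2)
        sol = pwls_solve(np.eye(4), z, penalty=1e12 * G)
        basis = np.column_stack([np.ones(4), np.arange(4.0)])
        line = basis @ np.linalg.lstsq(basis, z, rcond=None)[0]
        np.testing.assert_allclose(sol, line, atol=1e-4)

    def test_collinear_columns_detected(self):
        C = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(RankDeficiencyError):
            pwls_solve(C.T @ C, C.T @ np.arange(10.0))


class TestBackfitting:
    def test_no_smooths_equals_single_pwls(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(30), rng.normal(size=30)])
        w = rng.uniform(0.5, 2.0, 30)
        z = rng.normal(size=30)
        coefs, _, cycles = backfit_cycle(X, [], w, z)
        direct = pwls_solve(X.T @ (w[:, None] * X), X.T @ (w * z))
        np.testing.assert_allclose(coefs["beta"], direct, atol=1e-12)
        assert cycles == 1

    def _orthogonal_problem(self):
        n = 50
        X = np.ones((n, 1))
        u = np.linspace(-1, 1, n)
        Z = np.column_stack([u, u**2 - np.mean(u**2)])   # both W-orthogonal to 1
        G = np.eye(2)
        rng = np.random.default_rng(2)
        z = 1.0 + 0.5 * u + rng.normal(0, 0.1, n)
        smooth = {"Z": Z, "G": G, "lambda": 0.5,
                  "transfer_N": np.zeros((2, 0)), "beta_targets": []}
        return X, [smooth], np.ones(n), z

    def test_orthogonal_designs_converge_in_one_cycle(self):
        X, smooths, w, z = self._orthogonal_problem()
        one, _, _ = backfit_cycle(X, smooths, w, z, control=Control(max_backfit=1))
        again, _, _ = backfit_cycle(X, smooths, w, z, coefs=one)
        np.testing.assert_allclose(one["beta"], again["beta"], atol=1e-10)
        np.testing.assert_allclose(one["gamma"][0], again["gamma"][0], atol=1e-10)

    def test_fixed_point_idempotence(self):
        X, smooths, w, z = self._orthogonal_problem()
        conv, lam, _ = backfit_cycle(X, smooths, w, z)
        once_more, _, _ = backfit_cycle(X, smooths, w, z, coefs=conv, lambdas=lam)
        eta_a = X @ conv["beta"] + smooths[0]["Z"] @ conv["gamma"][0]
        eta_b = X @ once_more["beta"] + smooths[0]["Z"] @ once_more["gamma"][0]
        assert np.max(np.abs(eta_a - eta_b)) < 1e-10

    def test_fixed_lambda_is_never_updated(self):
        X, smooths, w, z = self._orthogonal_problem()
        _, lam, _ = backfit_cycle(X, smooths, w, z)
        assert lam == [0.5]


class TestInnerIteration:
    def test_gaussian_mu_step_is_wls_in_one_iteration(self):
        fam = get_family("NO")
        y = np.array([0.0, 1.0, 3.0])
        X = np.column_stack([np.ones(3), np.array([0.0, 1.0, 2.0])])
        theta = {"mu": np.full(3, y.mean()), "sigma": np.full(3, 1.0)}
        coefs, eta, trace = inner_iteration(fam, "mu", y, X, [], theta,
                                            control=Control(max_inner=1))
        np.testing.assert_allclose(coefs["beta"], [-1 / 6, 3 / 2], atol=1e-10)

    def test_bcpe_mu_step_deviance_monotone(self):
        rng = np.random.default_rng(6)
        fam = get_family("BCPE")
        n = 300
        age = rng.uniform(2, 18, n)
        th_true = {"mu": 80 + 5 * age, "sigma": np.full(n, 0.05),
                   "nu": np.full(n, 1.0), "tau": np.full(n, 2.0)}
        y = fam.ppf(rng.random(n), th_true)
        X = np.column_stack([np.ones(n), age])
        theta = {"mu": np.full(n, float(y.mean())), "sigma": np.full(n, 0.08),
                 "nu": np.full(n, 1.0), "tau": np.full(n, 2.0)}
        _, _, trace = inner_iteration(fam, "mu", y, X, [], theta)
        assert all(b <= a + 1e-8 for a, b in zip(trace, trace[1:]))


class TestFitPooled:
    def test_three_point_closed_form(self):
        df = pd.DataFrame({"y": [0.0, 1.0, 3.0], "x": [0.0, 1.0, 2.0]})
        spec = ModelSpec(family="NO", formulas={"mu": "1 + x", "sigma": "1"},
                         response="y", control=Control(outer_tol=1e-9, inner_tol=1e-9))
        m = fit_pooled(spec, df)
        np.testing.assert_allclose(m.coefficients["mu"]["beta"], [-1 / 6, 3 / 2],
                                   atol=1e-8)
        assert np.exp(m.coefficients["sigma"]["beta"][0]) == pytest.approx(
            np.sqrt(1 / 18), abs=1e-6)

    def test_insufficient_data_rejected(self):
        df = pd.DataFrame({"y": [1.0, 2.0], "x": [0.0, 1.0]})
        spec = ModelSpec(family="NO", formulas={"mu": "1 + x + pb(x, n_intervals=4, degree=1)",
                                                "sigma": "1"}, response="y")
        with pytest.raises(SpecificationError):
            fit_pooled(spec, df)

    def test_heteroscedastic_gaussian_matches_alternating_ml_oracle(self, sbp_tables,
                                                                    sbp_spec):
        tables, _ = sbp_tables
        df = pd.concat(tables.values(), ignore_index=True)
        m = fit_pooled(sbp_spec, df, control=Control(outer_tol=1e-9, inner_tol=1e-9))

        # independent oracle: alternate WLS for beta and per-country ML variances
        X = np.column_stack([np.ones(len(df)), (df["sex"] == "male").astype(float),
                             df["bmi"].to_numpy()])
        y = df["sbp"].to_numpy()
        de = (df["country"] == "Germany").to_numpy()
        s = np.array([8.0, 8.0])
        for _ in range(200):
            w = np.where(de, 1 / s[0] ** 2, 1 / s[1] ** 2)
            beta = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * y))
            r = y - X @ beta
            s_new = np.array([np.sqrt(np.mean(r[de] ** 2)),
                              np.sqrt(np.mean(r[~de] ** 2))])
            if np.max(np.abs(s_new - s)) < 1e-12:
                s = s_new
                break
            s = s_new
        np.testing.assert_allclose(m.coefficients["mu"]["beta"], beta, atol=1e-6)
        fitted_s = np.exp(m.coefficients["sigma"]["beta"][0]
                          + m.coefficients["sigma"]["beta"][1] * np.array([0.0, 1.0]))
        np.testing.assert_allclose(fitted_s, s, rtol=1e-6)

    def test_recovers_truth_within_monte_carlo_error(self, sbp_tables, sbp_spec):
        tables, t = sbp_tables
        df = pd.concat(tables.values(), ignore_index=True)
        m = fit_pooled(sbp_spec, df)
        # GLS standard errors at the generating truth
        X = np.column_stack([np.ones(len(df)), (df["sex"] == "male").astype(float),
                             df["bmi"].to_numpy()])
        sig = np.exp(t["beta20"] + t["beta21_spain"] * (df["country"] == "Spain"))
        w = 1.0 / sig.to_numpy() ** 2
        se_mu = np.sqrt(np.diag(np.linalg.inv(X.T @ (w[:, None] * X))))
        # data are female-referenced: male effect = -beta11_female
        truth_mu = np.array([t["beta10"] + t["beta11_female"], -t["beta11_female"],
                             t["beta12_bmi"]])
        est_mu = m.coefficients["mu"]["beta"]
        assert np.all(np.abs(est_mu - truth_mu) < 3 * se_mu)
        n_de = (df["country"] == "Germany").sum()
        n_es = len(df) - n_de
        se_sig = np.array([np.sqrt(1 / (2 * n_de)),
                           np.sqrt(1 / (2 * n_de) + 1 / (2 * n_es))])
        est_sig = m.coefficients["sigma"]["beta"]
        truth_sig = np.array([t["beta20"], t["beta21_spain"]])
        assert np.all(np.abs(est_sig - truth_sig) < 3 * se_sig)

    def test_permutation_invariance(self, growth_no_pooled, growth_no_spec):
        m1 = fit_pooled(growth_no_spec, growth_no_pooled)
        perm = growth_no_pooled.sample(frac=1.0, random_state=99).reset_index(drop=True)
        m2 = fit_pooled(growth_no_spec, perm,
                        knots={"age": np.asarray(m1.plan["params"]["mu"]["smooths"][0]["knots"])})
        for k in ("mu", "sigma"):
            np.testing.assert_allclose(m1.coef_vector(k), m2.coef_vector(k), atol=1e-10)

    def test_huge_lambda_collapses_to_linear_fit(self, growth_no_pooled):
        smooth = ModelSpec(
            family="NO",
            formulas={"mu": "1 + age + pb(age, lambda=1e12)",
                      "sigma": "1 + age + pb(age, lambda=1e12)"},
            response="height")
        linear = ModelSpec(family="NO",
                           formulas={"mu": "1 + age", "sigma": "1 + age"},
                           response="height")
        ms = fit_pooled(smooth, growth_no_pooled)
        ml = fit_pooled(linear, growth_no_pooled)
        grid = pd.DataFrame({"age": np.linspace(2.2, 17.8, 25)})
        ts, tl = predict_parameters(ms, grid), predict_parameters(ml, grid)
        for k in ("mu", "sigma"):
            assert np.max(np.abs(ts[k] - tl[k]) / np.abs(tl[k])) < 1e-3

    def test_penalized_deviance_trace_monotone(self, growth_no_pooled):
        spec = ModelSpec(
            family="NO",
            formulas={"mu": "1 + age + pb(age, lambda=5)",
                      "sigma": "1 + age + pb(age, lambda=5)"},
            response="height")
        m = fit_pooled(spec, growth_no_pooled)
        trace = np.asarray(m._pen_trace)
        assert np.all(np.diff(trace) <= 1e-7 * (np.abs(trace[:-1]) + 1.0))

    def test_growth_no_recovers_mean_curve(self, growth_no_pooled, growth_no_spec):
        m = fit_pooled(growth_no_spec, growth_no_pooled)
        grid = pd.DataFrame({"age": np.linspace(2.2, 17.8, 20)})
        mu_hat = predict_parameters(m, grid)["mu"].to_numpy()
        mu_true = growth_truth_theta("growth_NO", grid["age"])["mu"]
        assert np.max(np.abs(mu_hat - mu_true) / mu_true) < 0.02
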