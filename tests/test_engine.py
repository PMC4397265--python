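"""Estimation engine: implied covariance, discrepancy, fitting,
robust rescaling, and inference helpers.

Independent oracles used here: per-cell brute-force covariance algebra,
multivariate-normal log-density identities, exhaustive grid search on
low-dimensional problems, and an independently coded likelihood fitter
(different matrix construction, parameter packing and optimizer) that
stands in for an external SEM program.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from fixedlinks import (
    FREE,
    FitOptions,
    ModelSpec,
    PopulationModel,
    SampleMoments,
    build_paper_model,
    fit,
    fixed,
    generate,
    implied_covariance,
    ml_discrepancy,
    satorra_bentler_scale,
    variance_z_test,
    wald_constraint_test,
)
from fixedlinks.model import WMC_NAMES

from conftest import random_spd


# ----------------------------------------------------------------------
# implied covariance
# ----------------------------------------------------------------------


class TestImpliedCovariance:
    def test_zero_loadings_identity_residuals(self):
        spec = ModelSpec(
            manifest_names=["y1", "y2"],
            latent_names=["F"],
            loadings={("y1", "F"): fixed(0.0), ("y2", "F"): fixed(0.0)},
            latent_variances={"F": fixed(1.0)},
            residual_variances={"y1": fixed(1.0), "y2": fixed(1.0)},
        )
        assert np.allclose(implied_covariance(spec, {}), np.eye(2))

    def test_unit_loadings_no_residuals_gives_all_ones(self):
        spec = ModelSpec(
            manifest_names=["y1", "y2", "y3"],
            latent_names=["F"],
            loadings={(y, "F"): fixed(1.0) for y in ["y1", "y2", "y3"]},
            latent_variances={"F": fixed(1.0)},
            residual_variances={y: fixed(0.0) for y in ["y1", "y2", "y3"]},
        )
        assert np.allclose(implied_covariance(spec, {}), np.ones((3, 3)))

    def test_model5_matches_per_cell_formula(self):
        # independent route: sigma_ij = l_i l_j psi_c + g_i g_j psi_d (+ th_i)
        spec = build_paper_model(5)
        psi_c, psi_d = 0.0120, 0.0121
        th = [0.019, 0.024, 0.012, 0.030, 0.041]
        theta = {"Constant~~Constant": psi_c, "Dynamic~~Dynamic": psi_d}
        for name, t in zip(WMC_NAMES, th):
            theta[f"{name}~~{name}"] = t
        Sigma = implied_covariance(spec, theta)
        g = (0.36, 0.80, 0.99, 0.94, 0.64)
        for i in range(5):
            for j in range(5):
                expected = psi_c + g[i] * g[j] * psi_d + (th[i] if i == j else 0.0)
                assert Sigma[i, j] == pytest.approx(expected, abs=1e-12)

    def test_missing_free_parameter_raises(self):
        spec = build_paper_model(5)
        with pytest.raises(ValueError, match="missing"):
            implied_covariance(spec, {"Constant~~Constant": 0.01})


# ----------------------------------------------------------------------
# discrepancy function
# ----------------------------------------------------------------------


class TestMLDiscrepancy:
    def test_zero_iff_equal(self):
        rng = np.random.default_rng(0)
        S = random_spd(rng, 4)
        assert ml_discrepancy(S, S) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_identity_vs_scaled_identity(self):
        # F(I2, diag(2,2)) = 2 ln 2 + 2*(1/2) - 2 = 2 ln 2 - 1
        val = ml_discrepancy(np.eye(2), 2 * np.eye(2))
        assert val == pytest.approx(2 * np.log(2) - 1, abs=1e-12)

    def test_equals_normal_loglikelihood_ratio(self):
        # F_ML(S_mle, Sigma) = 2 * (mean logpdf at S_mle - mean logpdf at
        # Sigma) for centered data whose divisor-n covariance is S_mle
        rng = np.random.default_rng(42)
        X = rng.standard_normal((60, 3)) @ random_spd(rng, 3)
        X -= X.mean(axis=0)
        S_mle = (X.T @ X) / len(X)
        Sigma = random_spd(rng, 3)
        l_sat = stats.multivariate_normal(np.zeros(3), S_mle).logpdf(X).mean()
        l_mod = stats.multivariate_normal(np.zeros(3), Sigma).logpdf(X).mean()
        assert ml_discrepancy(S_mle, Sigma) == pytest.approx(2 * (l_sat - l_mod), abs=1e-10)

    def test_rejects_indefinite_input(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="Sigma"):
            ml_discrepancy(np.eye(2), bad)
        with pytest.raises(ValueError, match="S"):
            ml_discrepancy(bad, np.eye(2))


# ----------------------------------------------------------------------
# fitting
# ----------------------------------------------------------------------


def _toy_two_indicator(psi_free=True):
    """Single factor, two indicators, loadings fixed to 1, residuals
    fixed to known values; the latent variance is the only free one."""
    return ModelSpec(
        manifest_names=["y1", "y2"],
        latent_names=["F"],
        loadings={("y1", "F"): fixed(1.0), ("y2", "F"): fixed(1.0)},
        latent_variances={"F": FREE if psi_free else fixed(0.5)},
        residual_variances={"y1": fixed(0.3), "y2": fixed(0.4)},
    )


class TestFit:
    def test_saturated_one_factor_three_indicators(self, wmc_moments):
        # 3 free loadings + 3 residuals = 6 = p(p+1)/2: exact fit
        spec = ModelSpec(
            manifest_names=["Cond1", "Cond2", "Cond3"],
            latent_names=["F"],
            loadings={(y, "F"): FREE for y in ["Cond1", "Cond2", "Cond3"]},
            latent_variances={"F": fixed(1.0)},
        )
        res = fit(spec, wmc_moments.subset(["Cond1", "Cond2", "Cond3"]))
        assert res.df == 0
        assert res.F_min == pytest.approx(0.0, abs=1e-8)
        assert res.T == pytest.approx(0.0, abs=1e-5)

    def test_one_parameter_toy_matches_grid_search(self):
        spec = _toy_two_indicator()
        S = np.array([[0.9, 0.45], [0.45, 1.0]])
        moments = SampleMoments(S=S, names=["y1", "y2"], n=100)
        res = fit(spec, moments)
        grid = np.linspace(0.01, 2.0, 20001)
        F = [ml_discrepancy(S, implied_covariance(spec, {"F~~F": g})) for g in grid]
        psi_grid = grid[int(np.argmin(F))]
        assert res.theta_hat["F~~F"] == pytest.approx(psi_grid, abs=1e-4)

    def test_two_parameter_toy_matches_grid_search(self):
        spec = ModelSpec(
            manifest_names=["y1", "y2"],
            latent_names=["F"],
            loadings={("y1", "F"): fixed(1.0), ("y2", "F"): fixed(1.0)},
            latent_variances={"F": FREE},
            residual_variances={"y1": FREE, "y2": fixed(0.4)},
        )
        S = np.array([[1.1, 0.5], [0.5, 0.95]])
        moments = SampleMoments(S=S, names=["y1", "y2"], n=80)
        res = fit(spec, moments)
        psis = np.linspace(0.2, 1.0, 401)
        thetas = np.linspace(0.2, 1.2, 501)
        best = min(
            ((p, t) for p in psis for t in thetas),
            key=lambda pt: ml_discrepancy(
                S, implied_covariance(spec, {"F~~F": pt[0], "y1~~y1": pt[1]})
            ),
        )
        assert res.theta_hat["F~~F"] == pytest.approx(best[0], abs=2.5e-3)
        assert res.theta_hat["y1~~y1"] == pytest.approx(best[1], abs=2.5e-3)

    def test_model1_on_study_block(self, wmc_moments):
        # printed statistic is SB-scaled, ours plain ML on 2-dp input:
        # same ballpark, positive standardized loadings
        res = fit(build_paper_model(1), wmc_moments)
        assert res.converged
        assert res.df == 5
        assert 5.0 < res.T < 12.0
        stds = [res.standardized[f"WMC=~{y}"] for y in WMC_NAMES]
        assert all(0 < s < 1 for s in stds)

    def test_recovers_population_values_exactly_at_population_moments(self, population):
        spec = build_paper_model("structural_fixedlinks")
        Sigma = population.implied_covariance()
        moments = SampleMoments(S=Sigma, names=spec.manifest_names, n=200)
        res = fit(spec, moments)
        assert res.F_min == pytest.approx(0.0, abs=1e-9)
        truth = population.to_theta()
        for key, val in truth.items():
            assert res.theta_hat[key] == pytest.approx(val, abs=1e-4)

    def test_consistency_estimates_approach_truth_with_n(self, population):
        spec = build_paper_model("structural_fixedlinks")
        truth = population.to_theta()
        errs = {}
        for n in (500, 50_000):
            data = generate(population, n, seed=11)
            res = fit(spec, SampleMoments.from_raw(data))
            errs[n] = max(abs(res.theta_hat[k] - truth[k]) / max(abs(truth[k]), 0.01)
                          for k in truth)
        assert errs[50_000] < errs[500]
        assert errs[50_000] < 0.05

    def test_scale_equivariance_free_loadings(self, wmc_moments):
        # rescaling a manifest leaves F/T/df unchanged when its loading
        # is free ...
        spec = build_paper_model(1)
        res = fit(spec, wmc_moments)
        k = 3.0
        D = np.diag([k, 1, 1, 1, 1])
        S2 = D @ wmc_moments.S @ D
        res2 = fit(spec, SampleMoments(S=S2, names=wmc_moments.names, n=200))
        assert res2.F_min == pytest.approx(res.F_min, abs=1e-7)
        assert res2.theta_hat["WMC=~Cond1"] == pytest.approx(k * res.theta_hat["WMC=~Cond1"], rel=1e-4)
        assert res2.theta_hat["Cond1~~Cond1"] == pytest.approx(k**2 * res.theta_hat["Cond1~~Cond1"], rel=1e-4)

    def test_scale_equivariance_violated_with_fixed_links(self, wmc_moments):
        # ... and is deliberately broken when loadings are fixed
        spec = build_paper_model(5)
        res = fit(spec, wmc_moments)
        D = np.diag([3.0, 1, 1, 1, 1])
        S2 = D @ wmc_moments.S @ D
        res2 = fit(spec, SampleMoments(S=S2, names=wmc_moments.names, n=200))
        assert abs(res2.F_min - res.F_min) > 1e-3

    def test_standardized_solution_invariant_to_metric(self, wmc_moments):
        # congeneric model: identical standardized solution on S and on
        # the correlation matrix derived from S
        rng = np.random.default_rng(5)
        sds = rng.uniform(0.5, 2.0, 5)
        S = wmc_moments.S * np.outer(sds, sds)
        cov = SampleMoments(S=S, names=wmc_moments.names, n=200)
        res_cov = fit(build_paper_model(1), cov)
        res_cor = fit(build_paper_model(1), cov.to_correlation())
        for key, val in res_cov.standardized.items():
            assert res_cor.standardized[key] == pytest.approx(val, abs=1e-6)

    def test_standardized_variance_decomposition_sums_to_one(self, wmc_moments):
        # uncorrelated latents: sum of squared standardized loadings plus
        # standardized residual variance = 1 per manifest
        res = fit(build_paper_model(5), wmc_moments)
        for y in WMC_NAMES:
            total = (
                res.standardized[f"Constant=~{y}"] ** 2
                + res.standardized[f"Dynamic=~{y}"] ** 2
                + res.standardized[f"{y}~~{y}"]
            )
            assert total == pytest.approx(1.0, abs=1e-6)

    def test_multiplier_configurable(self, wmc_moments):
        res_n1 = fit(build_paper_model(5), wmc_moments)
        res_n = fit(build_paper_model(5), wmc_moments, FitOptions(multiplier=200))
        assert res_n.T == pytest.approx(res_n1.T * 200 / 199, rel=1e-6)

    def test_heywood_case_flagged(self):
        # force a negative residual: y1 almost perfectly explained
        rng = np.random.default_rng(3)
        f = rng.standard_normal(60)
        X = pd.DataFrame({
            "y1": f + 0.01 * rng.standard_normal(60),
            "y2": 0.8 * f + rng.standard_normal(60),
            "y3": 0.7 * f + rng.standard_normal(60),
            "y4": -0.1 * f + rng.standard_normal(60),
        })
        spec = ModelSpec(
            manifest_names=list(X.columns),
            latent_names=["F"],
            loadings={(y, "F"): FREE for y in X.columns},
            latent_variances={"F": fixed(1.0)},
        )
        res = fit(spec, SampleMoments.from_raw(X))
        if any(res.theta_hat[f"{y}~~{y}"] < 0 for y in X.columns):
            assert res.heywood

    def test_first_free_loading_sign_nonnegative(self, full_moments):
        res = fit(build_paper_model("structural_cfa"), full_moments)
        assert res.theta_hat["WMC=~Cond1"] >= 0
        # Reasoning scaling loading is fixed positive, so the structural
        # path sign is meaningful
        assert res.standardized["Reasoning~WMC"] > 0


# ----------------------------------------------------------------------
# dual-route oracle (stand-in for an external SEM program)
# ----------------------------------------------------------------------


def _oracle_congeneric_fit(S, n_ind, psi_fixed=1.0):
    """Independently coded one-factor ML fit.

    Builds Sigma cell by cell (no shared code with the engine), packs
    parameters as (loadings..., residuals...) and minimizes with
    Nelder-Mead from different starts.
    """

    def sigma(x):
        lam, th = x[:n_ind], x[n_ind:]
        M = np.empty((n_ind, n_ind))
        for i in range(n_ind):
            for j in range(n_ind):
                M[i, j] = lam[i] * lam[j] * psi_fixed + (th[i] if i == j else 0.0)
        return M

    p = n_ind
    sign_s, logdet_s = np.linalg.slogdet(S)

    def obj(x):
        M = sigma(x)
        sign, logdet = np.linalg.slogdet(M)
        if sign <= 0:
            return 1e8
        return logdet - logdet_s + np.trace(np.linalg.solve(M, S)) - p

    x0 = np.concatenate([np.full(n_ind, 0.7), np.full(n_ind, 0.5)])
    res = optimize.minimize(obj, x0, method="Nelder-Mead",
                            options={"maxfev": 40000, "fatol": 1e-13, "xatol": 1e-9})
    res = optimize.minimize(obj, res.x, method="Nelder-Mead",
                            options={"maxfev": 40000, "fatol": 1e-14, "xatol": 1e-10})
    lam = res.x[:n_ind]
    if lam[0] < 0:
        lam = -lam
    return res.fun, lam, res.x[n_ind:]


@pytest.mark.parametrize("seed", [101, 202, 303, 404, 505])
def test_fit_agrees_with_independent_likelihood_fitter(seed):
    """Five random small one-factor models: engine F_min within 1e-6 and
    estimates within 1e-4 of an independently coded ML fitter."""
    rng = np.random.default_rng(seed)
    n_ind = int(rng.integers(3, 5))
    lam_true = rng.uniform(0.4, 0.9, n_ind)
    th_true = rng.uniform(0.3, 0.8, n_ind)
    Sigma_pop = np.outer(lam_true, lam_true) + np.diag(th_true)
    X = rng.multivariate_normal(np.zeros(n_ind), Sigma_pop, size=150)
    S = np.cov(X, rowvar=False, ddof=1)
    names = [f"y{i}" for i in range(n_ind)]
    spec = ModelSpec(
        manifest_names=names,
        latent_names=["F"],
        loadings={(y, "F"): FREE for y in names},
        latent_variances={"F": fixed(1.0)},
    )
    res = fit(spec, SampleMoments(S=S, names=names, n=150))
    F_oracle, lam_o, th_o = _oracle_congeneric_fit(S, n_ind)
    assert res.F_min == pytest.approx(F_oracle, abs=1e-6)
    for i, y in enumerate(names):
        assert res.theta_hat[f"F=~{y}"] == pytest.approx(lam_o[i], abs=1e-4)
        assert res.theta_hat[f"{y}~~{y}"] == pytest.approx(th_o[i], abs=1e-4)


# ----------------------------------------------------------------------
# Satorra-Bentler rescaling
# ----------------------------------------------------------------------


class TestSatorraBentler:
    def test_scaling_near_one_under_normality(self, population):
        data = generate(population, 50_000, seed=21)
        moments = SampleMoments.from_raw(data)
        res = fit(build_paper_model("structural_fixedlinks"), moments)
        T_scaled, c = satorra_bentler_scale(res.spec, moments, res)
        assert c == pytest.approx(1.0, abs=0.02)
        assert T_scaled * c == pytest.approx(res.T, rel=1e-12)

    def test_scaling_exceeds_one_with_heavy_tails(self):
        pop = PopulationModel(error_family="scaled_t", t_df=5.0)
        cs = []
        for seed in (31, 32, 33):
            data = generate(pop, 4000, seed=seed)
            moments = SampleMoments.from_raw(data)
            res = fit(build_paper_model("structural_fixedlinks"), moments)
            _, c = satorra_bentler_scale(res.spec, moments, res)
            cs.append(c)
        assert np.mean(cs) > 1.05

    def test_requires_raw_data(self, wmc_moments):
        res = fit(build_paper_model(5), wmc_moments)
        with pytest.raises(ValueError, match="raw data"):
            satorra_bentler_scale(res.spec, wmc_moments, res)


# ----------------------------------------------------------------------
# variance z-test and Wald test
# ----------------------------------------------------------------------


class TestVarianceZTest:
    def test_fixed_variance_rejected(self, wmc_moments):
        res = fit(build_paper_model(1), wmc_moments)
        with pytest.raises(ValueError, match="not a free parameter"):
            variance_z_test(res, "WMC")

    def test_null_dynamic_variance_rejection_rate(self):
        # data generated with zero dynamic variance: the |z| > 1.96 rate
        # should be near or below nominal
        from fixedlinks.simulate import null_dynamic_population

        pop = null_dynamic_population()
        spec = build_paper_model(5)
        hits = total = 0
        for seed in range(40):
            data = generate(pop, 200, seed=1000 + seed)
            moments = SampleMoments.from_raw(data[list(WMC_NAMES)])
            res = fit(spec, moments)
            if not res.converged:
                continue
            z, p = variance_z_test(res, "Dynamic")
            if np.isfinite(z):
                total += 1
                hits += p < 0.05
        assert total >= 30
        assert hits / total <= 0.15

    def test_power_at_study_conditions(self, population):
        # with the study's variances at n = 200 both z-tests should be
        # significant in the large majority of replications
        spec = build_paper_model(5)
        sig_c = sig_d = total = 0
        for seed in range(30):
            data = generate(population, 200, seed=2000 + seed)
            res = fit(spec, SampleMoments.from_raw(data[list(WMC_NAMES)]))
            if not res.converged:
                continue
            total += 1
            sig_c += variance_z_test(res, "Constant")[1] < 0.05
            sig_d += variance_z_test(res, "Dynamic")[1] < 0.05
        assert sig_c / total > 0.8
        assert sig_d / total > 0.6


class TestWaldTest:
    def test_zero_at_the_estimate(self, full_moments):
        spec = build_paper_model("structural_fixedlinks")
        res = fit(spec, full_moments)
        beta = res.standardized["Reasoning~Dynamic"]
        W, p, _ = wald_constraint_test(spec, full_moments, ("Reasoning", "Dynamic"), beta, fitresult=res)
        assert W == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_delta_method_matches_hand_formula(self, full_moments):
        # W must equal (beta - value)^2 / Var(beta) with Var(beta) from
        # the same delta-method variance, recomputed by hand here
        from fixedlinks.engine import _num_gradient, _standardized_path_fn

        spec = build_paper_model("structural_fixedlinks")
        res = fit(spec, full_moments)
        names = spec.free_parameter_names()
        x_hat = np.array([res.theta_hat[k] for k in names])
        g = _num_gradient(_standardized_path_fn(spec, names, "Reasoning~Dynamic"), x_hat)
        var_beta = float(g @ res.vcov @ g)
        value = 0.2
        W, _, beta = wald_constraint_test(spec, full_moments, ("Reasoning", "Dynamic"), value, fitresult=res)
        assert W == pytest.approx((beta - value) ** 2 / var_beta, rel=1e-8)

    def test_fit_difference_variant_agrees_in_order_of_magnitude(self, full_moments):
        spec = build_paper_model("structural_fixedlinks")
        res = fit(spec, full_moments)
        W_d, _, _ = wald_constraint_test(spec, full_moments, ("Reasoning", "Dynamic"), 0.68, fitresult=res)
        W_f, _, _ = wald_constraint_test(
            spec, full_moments, ("Reasoning", "Dynamic"), 0.68, fitresult=res, method="fit_difference"
        )
        assert W_f == pytest.approx(W_d, rel=0.5)
        assert W_f >= 0

    def test_unknown_path_rejected(self, full_moments):
        spec = build_paper_model("structural_fixedlinks")
        with pytest.raises(ValueError, match="not a free structural parameter"):
            wald_constraint_test(spec, full_moments, ("Reasoning", "Gf"), 0.5)


# ----------------------------------------------------------------------
# sample moments container
# ----------------------------------------------------------------------


class TestSampleMoments:
    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError, match="symmetric"):
            SampleMoments(S=np.array([[1.0, 0.5], [0.2, 1.0]]), names=["a", "b"], n=10)

    def test_rejects_indefinite(self):
        with pytest.raises(ValueError, match="positive definite"):
            SampleMoments(S=np.array([[1.0, 2.0], [2.0, 1.0]]), names=["a", "b"], n=10)

    def test_raw_consistency_enforced(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.standard_normal((30, 2)), columns=["a", "b"])
        with pytest.raises(ValueError, match="reproduce"):
            SampleMoments(S=np.eye(2), names=["a", "b"], n=30, raw=df)

    def test_from_raw_roundtrip(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.standard_normal((40, 3)), columns=list("abc"))
        m = SampleMoments.from_raw(df)
        assert m.n == 40
        assert np.allclose(m.S, np.cov(df.to_numpy().T, ddof=1))
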