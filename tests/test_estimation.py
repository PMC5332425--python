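"""ML discrepancy, summary-statistic fitting, FIML, EM, standard errors."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import minimize
from scipy.stats import multivariate_normal, norm

from latentchange.estimation import (GroupData, em_mvn, fiml_casewise_loglik,
                                     fit_fiml_raw, fit_ml_summary,
                                     ml_discrepancy)
from latentchange.model_core import ModelSpec, ParameterMatrixSet, implied_moments
from latentchange.sequence import build_group_model, build_step_model
from latentchange.simulate import study_config, simulate_group_data

from conftest import random_psd


class TestMlDiscrepancy:
    def test_zero_at_perfect_fit(self):
        rng = np.random.default_rng(1)
        s = random_psd(rng, 4)
        m = rng.normal(size=4)
        assert ml_discrepancy(m, s, m, s) == pytest.approx(0.0, abs=1e-12)

    def test_univariate_hand_value(self):
        # s2 = 1 against sigma2 = 2, equal means: ln 2 + 1/2 - 1
        f = ml_discrepancy([0.0], [[1.0]], [0.0], [[2.0]])
        assert f == pytest.approx(np.log(2) + 0.5 - 1.0, abs=1e-12)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_direct_formula_oracle(self, seed):
        rng = np.random.default_rng(seed)
        s, sig = random_psd(rng, 4), random_psd(rng, 4)
        m, mu = rng.normal(size=4), rng.normal(size=4)
        # independently coded evaluation via explicit inverse and determinant
        si = np.linalg.inv(sig)
        oracle = (np.log(np.linalg.det(sig)) - np.log(np.linalg.det(s))
                  + np.trace(s @ si) - 4 + (m - mu) @ si @ (m - mu))
        assert ml_discrepancy(m, s, mu, sig) == pytest.approx(oracle, rel=1e-10)
        assert ml_discrepancy(m, s, mu, sig) >= 0.0

    def test_equals_twice_gaussian_kl_by_monte_carlo(self):
        # F = 2 KL(N(m,S) || N(mu,Sigma)), estimated from simulated draws
        rng = np.random.default_rng(7)
        s, sig = random_psd(rng, 3), random_psd(rng, 3)
        m, mu = rng.normal(size=3), rng.normal(size=3)
        x = rng.multivariate_normal(m, s, size=400_000)
        diffs = (multivariate_normal.logpdf(x, m, s)
                 - multivariate_normal.logpdf(x, mu, sig))
        kl_mc = diffs.mean()
        mc_se = diffs.std(ddof=1) / np.sqrt(diffs.size)
        assert ml_discrepancy(m, s, mu, sig) == pytest.approx(
            2 * kl_mc, abs=8 * mc_se)

    def test_singular_implied_covariance_flagged_nonfinite(self):
        f = ml_discrepancy([0.0, 0.0], np.eye(2), [0.0, 0.0], np.zeros((2, 2)))
        assert not np.isfinite(f)


def _exact_model2_data(seed=0):
    """Moments generated exactly from a known Model 2 configuration."""
    spec = build_step_model("M2")
    truth = {"kappa1_G1": 3.4, "kappa2_G1": 0.2, "phi1_G1": 0.5,
             "phi2_G1": 0.3, "phi12_G1": -0.1,
             "theta_t1_G1": 0.2, "theta_t2_G1": 0.15,
             "theta_c1_G1": 0.05, "theta_c2_G1": 0.02,
             "kappa1_G2": 3.5, "phi1_G2": 0.4, "zeta1_G2": 0.08,
             "zeta2_G2": 0.05, "theta_t1_G2": 0.2, "theta_t2_G2": 0.18,
             "theta_c1_G2": 0.03, "theta_c2_G2": 0.03}
    from latentchange.estimation import CompiledSpec
    comp = CompiledSpec(spec)
    comp.update(np.array([truth[lab] for lab in comp.labels]))
    data = {}
    for gid in ("G1", "G2"):
        mu, sigma = comp.implied(gid)
        data[gid] = GroupData.from_moments(gid, mu, sigma, 200)
    return spec, truth, data


class TestFitMlSummary:
    def test_recovers_generating_parameters_with_zero_chisq(self):
        spec, truth, data = _exact_model2_data()
        fit = fit_ml_summary(spec, data, compute_se=False)
        assert fit.converged
        assert fit.chi_square == pytest.approx(0.0, abs=1e-6)
        for lab, val in truth.items():
            assert fit.estimates[lab] == pytest.approx(val, abs=1e-4)

    def test_group_contributions_sum_to_total(self, model2_fit):
        assert sum(model2_fit.chi_square_by_group.values()) == pytest.approx(
            model2_fit.chi_square, abs=1e-8)
        assert model2_fit.chi_square == pytest.approx(
            2 * (model2_fit.loglik_saturated - model2_fit.loglik_model), abs=1e-8)

    def test_chi_square_invariant_to_group_relabeling(self, table1):
        fit_a = fit_ml_summary(build_step_model("M2", ("G1", "G2")), table1,
                               compute_se=False)
        swapped = {"A": GroupData.from_moments("A", table1["G1"].mean,
                                               table1["G1"].cov, table1["G1"].n),
                   "B": GroupData.from_moments("B", table1["G2"].mean,
                                               table1["G2"].cov, table1["G2"].n)}
        fit_b = fit_ml_summary(build_step_model("M2", ("A", "B")), swapped,
                               compute_se=False)
        assert fit_b.chi_square == pytest.approx(fit_a.chi_square, abs=1e-6)

    def test_n_minus_one_convention_rescales_chi_square(self, table1):
        fit_n = fit_ml_summary(build_step_model("M1"), table1, compute_se=False)
        fit_n1 = fit_ml_summary(build_step_model("M1"), table1,
                                compute_se=False, n_convention="n-1")
        # both groups shrink by one case; same minimizing parameters
        expect = sum((n - 1) / n * c for (_, c), n in
                     zip(fit_n.chi_square_by_group.items(),
                         fit_n.n_by_group.values()))
        assert fit_n1.chi_square == pytest.approx(expect, rel=5e-3)

    def test_nested_models_weakly_decrease_discrepancy(self, table1):
        chis = [fit_ml_summary(build_step_model(s), table1, compute_se=False
                               ).chi_square for s in ("M1", "M2", "M3")]
        assert chis[0] >= chis[1] - 1e-6 >= chis[2] - 2e-6

    def test_heywood_case_reported_not_truncated(self):
        # implied moments built from a negative change-factor variance are a
        # legal covariance matrix; the fit should land on the negative value
        # and warn rather than silently truncate
        spec, truth, _ = _exact_model2_data()
        truth = dict(truth, phi2_G1=-0.05)
        from latentchange.estimation import CompiledSpec
        comp = CompiledSpec(build_step_model("M2"))
        comp.update(np.array([truth[lab] for lab in comp.labels]))
        data = {gid: GroupData.from_moments(gid, *comp.implied(gid), n=500)
                for gid in ("G1", "G2")}
        fit = fit_ml_summary(build_step_model("M2"), data, compute_se=False)
        assert fit.estimates["phi2_G1"] == pytest.approx(-0.05, abs=1e-3)
        assert any("Heywood" in w for w in fit.warnings)
        bounded = fit_ml_summary(build_step_model("M2"), data,
                                 compute_se=False, variance_floor=0.0)
        assert bounded.estimates["phi2_G1"] >= -1e-12

    def test_missing_group_data_raises(self, table1):
        with pytest.raises(ValueError, match="G2"):
            fit_ml_summary(build_step_model("M2"), {"G1": table1["G1"]})


class TestFiml:
    def test_complete_data_equals_summary_ml(self):
        cfg = study_config(seed=11, missing_prob=0.0)
        data = simulate_group_data(cfg)
        f_fiml = fit_fiml_raw(build_step_model("M2"), data, compute_se=False)
        moments = {g: GroupData.from_moments(g, *gd.moments())
                   for g, gd in data.items()}
        f_ml = fit_ml_summary(build_step_model("M2"), moments, compute_se=False)
        assert abs(f_fiml.chi_square - f_ml.chi_square) < 1e-4
        for lab in f_ml.estimates:
            assert f_fiml.estimates[lab] == pytest.approx(
                f_ml.estimates[lab], abs=1e-4)

    def test_group_contributions_sum_under_missingness(self):
        data = simulate_group_data(study_config(seed=5))
        fit = fit_fiml_raw(build_step_model("M2"), data, compute_se=False)
        assert fit.converged
        assert sum(fit.chi_square_by_group.values()) == pytest.approx(
            fit.chi_square, abs=1e-8)
        assert fit.chi_square >= -1e-6

    def test_casewise_loglik_single_case_is_normal_density(self):
        pms = build_group_model("A", "G1")
        pms.mats["kappa"][0] = 3.0
        pms.mats["phi"][0, 0] = 0.5
        pms.mats["theta_eps"][:] += 0.2 * np.eye(4)
        spec = ModelSpec(groups={"G1": pms})
        mu, sigma = implied_moments(pms)
        row = np.array([[3.3, np.nan, np.nan, np.nan]])
        gd = GroupData.from_raw("G1", row)
        ll = fiml_casewise_loglik(spec, {"G1": gd})
        assert ll == pytest.approx(
            norm.logpdf(3.3, loc=mu[0], scale=np.sqrt(sigma[0, 0])), abs=1e-10)

    def test_all_missing_cases_excluded_with_count(self):
        arr = np.array([[1.0, 2.0, 3.0, 4.0], [np.nan] * 4])
        with pytest.warns(UserWarning, match="all-missing"):
            gd = GroupData.from_raw("G1", arr)
        assert gd.raw.shape[0] == 1


class TestEmMvn:
    def test_complete_data_reduces_to_sample_moments(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(60, 3))
        mu, sigma, ll, _ = em_mvn(x)
        assert np.allclose(mu, x.mean(axis=0), atol=1e-10)
        assert np.allclose(sigma, np.cov(x, rowvar=False, ddof=0), atol=1e-8)

    def test_matches_direct_mle_optimizer_on_missing_data(self):
        # independent oracle: maximize the observed-data loglik directly over
        # the mean and covariance Cholesky factor
        rng = np.random.default_rng(9)
        x = rng.multivariate_normal([0, 1, 2], random_psd(rng, 3), size=60)
        x[rng.random(x.shape) < 0.2] = np.nan
        x = x[~np.isnan(x).all(axis=1)]
        mu_em, sig_em, ll_em, _ = em_mvn(x, tol=1e-13)

        from latentchange.estimation import _pattern_loglik, _split_patterns
        patterns = _split_patterns(x)
        tril = np.tril_indices(3)

        def nll(v):
            mu = v[:3]
            chol = np.zeros((3, 3))
            chol[tril] = v[3:]
            sigma = chol @ chol.T
            ll = _pattern_loglik(mu, sigma, patterns)
            return -ll if np.isfinite(ll) else 1e8

        chol0 = np.linalg.cholesky(sig_em + 0.1 * np.eye(3))
        v0 = np.concatenate([mu_em + 0.1, chol0[tril]])
        res = minimize(nll, v0, method="Nelder-Mead",
                       options={"maxiter": 40000, "maxfev": 40000,
                                "xatol": 1e-10, "fatol": 1e-12})
        assert -res.fun == pytest.approx(ll_em, abs=1e-5)
        assert np.allclose(res.x[:3], mu_em, atol=1e-3)


class TestStandardErrors:
    def test_known_variance_mean_se_closed_form(self):
        # single indicator, single occasion, fixed unit variance: the only
        # free parameter is the mean, whose SE must be sigma / sqrt(n)
        pms = ParameterMatrixSet(m=1, p=1, q=1, r=1)
        pms.mats["lambda_y"][:] = 1.0
        pms.mats["gamma"][:] = 1.0
        pms.set_free("kappa", 0, start=0.0, label="mean")
        pms.mats["theta_eps"][0, 0] = 0.0
        pms.mats["phi"][0, 0] = 1.0   # fixed known variance
        spec = ModelSpec(groups={"G1": pms})
        n = 400
        data = {"G1": GroupData.from_moments("G1", [0.3], [[1.0]], n)}
        fit = fit_ml_summary(spec, data)
        assert fit.se["mean"] == pytest.approx(1.0 / np.sqrt(n), rel=0.01)
        assert fit.estimates["mean"] == pytest.approx(0.3, abs=1e-6)

    def test_fixed_parameters_have_no_se_rows(self, model2_fit):
        assert set(model2_fit.se) == set(model2_fit.estimates)
        assert "lambda" not in " ".join(model2_fit.se)
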