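"""Parcel construction, descriptives, reliability, normality, MCAR test."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kurtosis as sp_kurtosis
from scipy.stats import skew as sp_skew

from latentchange.screening import (cronbach_alpha, descriptives,
                                    little_mcar_test, make_parcels,
                                    mardia_tests)


def exact_cov_sample(rng, n, cov, mean=None):
    """Draws transformed so that the SAMPLE (ddof=1) covariance is exactly
    ``cov`` and the sample mean exactly ``mean`` — closed-form checks on
    covariance-based statistics become deterministic."""
    p = cov.shape[0]
    x = rng.normal(size=(n, p))
    x -= x.mean(axis=0)
    chol_s = np.linalg.cholesky(np.cov(x, rowvar=False, ddof=1))
    x = x @ np.linalg.inv(chol_s).T @ np.linalg.cholesky(cov).T
    if mean is not None:
        x += mean
    return x


class TestParcels:
    def test_sixteen_items_split_into_two_parallel_forms(self):
        rng = np.random.default_rng(0)
        items = pd.DataFrame(rng.normal(size=(50, 16)),
                             columns=[f"it{i}" for i in range(16)])
        scores, assignment = make_parcels(items, 2, seed=4)
        assert sorted(len(v) for v in assignment.values()) == [8, 8]
        assert set(sum(assignment.values(), [])) == set(items.columns)
        assert list(scores.columns) == ["parcel1", "parcel2"]

    def test_same_seed_reproduces_different_seeds_differ(self):
        items = pd.DataFrame(np.zeros((5, 16)),
                             columns=[f"it{i}" for i in range(16)])
        _, a1 = make_parcels(items, 2, seed=1)
        _, a2 = make_parcels(items, 2, seed=1)
        _, a3 = make_parcels(items, 2, seed=2)
        assert a1 == a2
        assert a1 != a3

    def test_constant_items_give_constant_parcels(self):
        items = pd.DataFrame(np.full((10, 6), 2.5))
        scores, _ = make_parcels(items, 2, seed=0)
        assert np.allclose(scores.to_numpy(), 2.5)

    def test_parcel_grand_mean_equals_item_grand_mean(self):
        rng = np.random.default_rng(3)
        items = pd.DataFrame(rng.normal(size=(40, 16)))
        scores, _ = make_parcels(items, 2, seed=7)
        assert scores.to_numpy().mean() == pytest.approx(
            items.to_numpy().mean(), abs=1e-12)

    def test_missing_items_use_available_mean(self):
        items = pd.DataFrame({"a": [1.0, np.nan], "b": [3.0, 5.0]})
        scores, assignment = make_parcels(items, 1, seed=0)
        assert scores.iloc[0, 0] == pytest.approx(2.0)
        assert scores.iloc[1, 0] == pytest.approx(5.0)

    def test_too_many_parcels_rejected(self):
        items = pd.DataFrame(np.zeros((3, 4)))
        with pytest.raises(ValueError):
            make_parcels(items, 5, seed=0)


class TestDescriptives:
    def test_symmetric_two_point_variable_has_zero_skewness(self):
        x = pd.DataFrame({"a": [-1.0, 1.0] * 20, "b": np.arange(40.0)})
        out = descriptives(x)
        assert out.table.loc["a", "skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_bias_corrected_reference_formulas(self):
        # reference: scipy's bias-corrected skewness / excess kurtosis
        rng = np.random.default_rng(12)
        x = pd.DataFrame(rng.gamma(2.0, size=(200, 3)), columns=list("abc"))
        out = descriptives(x)
        for c in x.columns:
            assert out.table.loc[c, "skewness"] == pytest.approx(
                sp_skew(x[c], bias=False), abs=1e-10)
            assert out.table.loc[c, "kurtosis"] == pytest.approx(
                sp_kurtosis(x[c], bias=False), abs=1e-10)
            assert out.table.loc[c, "sd"] == pytest.approx(
                x[c].std(ddof=1), abs=1e-12)

    def test_large_normal_sample_near_zero_shape(self):
        rng = np.random.default_rng(5)
        x = pd.DataFrame({"a": rng.normal(size=100_000)})
        out = descriptives(x)
        assert abs(out.table.loc["a", "skewness"]) < 0.03
        assert abs(out.table.loc["a", "kurtosis"]) < 0.06

    def test_pairwise_complete_correlations_and_n(self):
        x = pd.DataFrame({"a": [1.0, 2, 3, 4, np.nan],
                          "b": [2.0, 1, 4, 3, 5],
                          "c": [1.0, np.nan, 2, 5, 4]})
        out = descriptives(x)
        assert out.table.loc["a", "n"] == 4
        mask = x[["a", "c"]].dropna()
        assert out.correlations.loc["a", "c"] == pytest.approx(
            mask["a"].corr(mask["c"]), abs=1e-12)

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError, match="zero-variance"):
            descriptives(pd.DataFrame({"a": [1.0, 1.0, 1.0]}))


class TestCronbachAlpha:
    def test_compound_symmetry_matches_spearman_brown(self):
        # k = 8 parallel items at rho = 0.5: alpha = 8*0.5 / (1 + 7*0.5)
        rng = np.random.default_rng(8)
        k, rho = 8, 0.5
        cov = np.full((k, k), rho) + (1 - rho) * np.eye(k)
        x = pd.DataFrame(exact_cov_sample(rng, 100, cov))
        assert cronbach_alpha(x) == pytest.approx(
            k * rho / (1 + (k - 1) * rho), abs=1e-10)

    def test_uncorrelated_items_near_zero(self):
        rng = np.random.default_rng(2)
        x = pd.DataFrame(exact_cov_sample(rng, 200, np.eye(6)))
        assert abs(cronbach_alpha(x)) < 1e-10

    def test_duplicated_item_drives_alpha_to_one(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=100)
        x = pd.DataFrame({"a": base, "b": base})
        assert cronbach_alpha(x) == pytest.approx(1.0, abs=1e-12)

    def test_invariant_to_item_shifts(self):
        rng = np.random.default_rng(4)
        x = pd.DataFrame(rng.normal(size=(80, 5)))
        assert cronbach_alpha(x + 100.0) == pytest.approx(
            cronbach_alpha(x), abs=1e-10)

    def test_single_item_rejected(self):
        with pytest.raises(ValueError):
            cronbach_alpha(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))


class TestMardia:
    def test_matches_textbook_double_loop_on_hand_example(self):
        x = np.array([[1.0, 2.0], [2.0, 1.0], [3.0, 5.0], [4.0, 3.0],
                      [5.0, 4.5]])
        res = mardia_tests(x)
        # independent double-loop evaluation of b1p and b2p
        z = x - x.mean(axis=0)
        s_inv = np.linalg.inv(z.T @ z / len(x))
        n = len(x)
        b1 = sum((z[i] @ s_inv @ z[j]) ** 3 for i in range(n)
                 for j in range(n)) / n ** 2
        b2 = sum((z[i] @ s_inv @ z[i]) ** 2 for i in range(n)) / n
        assert res.b1p == pytest.approx(b1, abs=1e-10)
        assert res.b2p == pytest.approx(b2, abs=1e-10)
        assert res.skew_df == 4   # p(p+1)(p+2)/6 with p = 2

    def test_large_normal_sample_kurtosis_near_theoretical(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(100_000, 4))
        res = mardia_tests(x)
        assert res.b2p == pytest.approx(4 * 6, abs=0.2)   # p(p+2) = 24

    def test_type_one_error_calibration_under_normality(self):
        # decisions at the package's default alpha = 0.001 should be rare
        # under multivariate normality
        rng = np.random.default_rng(77)
        rejections_skew = rejections_kurt = 0
        reps = 300
        for _ in range(reps):
            res = mardia_tests(rng.normal(size=(400, 3)))
            rejections_skew += res.skew_p < 0.001
            rejections_kurt += res.kurtosis_p < 0.001
        assert rejections_skew / reps <= 0.02
        assert rejections_kurt / reps <= 0.02

    def test_contaminated_data_rejected(self):
        from latentchange.simulate import study_config, simulate
        cfg = study_config(seed=1, missing_prob=0.0)
        cfg.contamination = (0.15, 4.0)
        cfg.groups["G1"].n = 2000
        df = simulate(cfg)
        sub = df.loc[df.group == "G1"].drop(columns="group")
        res = mardia_tests(sub)
        assert res.kurtosis_p < 0.001 and not res.kurtosis_normal

    def test_singular_covariance_rejected(self):
        x = np.column_stack([np.arange(10.0), np.arange(10.0)])
        with pytest.raises(ValueError, match="singular"):
            mardia_tests(x)


class TestLittleMcar:
    def test_posttest_dropout_pattern_df(self):
        # complete cases plus missing-both-T2 cases: df = (4 + 2) - 4 = 2
        from latentchange.simulate import study_config, simulate
        df = simulate(study_config(seed=2))
        cols = ["pr1_t1", "pr2_t1", "pr1_t2", "pr2_t2"]
        res = little_mcar_test(df[cols])
        assert res.applicable
        assert res.df == 2
        assert res.n_patterns == 2

    def test_no_missingness_not_applicable(self):
        rng = np.random.default_rng(0)
        res = little_mcar_test(rng.normal(size=(50, 4)))
        assert not res.applicable

    def test_type_one_error_under_mcar(self):
        rng = np.random.default_rng(123)
        reps, rejections = 200, 0
        for _ in range(reps):
            x = rng.multivariate_normal(
                [0, 0, 0], [[1, .5, .4], [.5, 1, .5], [.4, .5, 1]], size=250)
            x[rng.random(250) < 0.25, 2] = np.nan
            rejections += little_mcar_test(x).p_value < 0.05
        # binomial(200, 0.05) two-sigma band
        assert 0.02 <= rejections / reps <= 0.09

    def test_power_against_mar_by_design(self):
        # missingness at T2 driven by the T1 score must be detected
        rng = np.random.default_rng(55)
        reps, rejections = 40, 0
        for _ in range(reps):
            x = rng.multivariate_normal([3.5, 3.5], [[0.5, 0.35], [0.35, 0.5]],
                                        size=1000)
            p_miss = np.where(x[:, 0] < 3.5, 0.35, 0.05)
            x[rng.random(1000) < p_miss, 1] = np.nan
            rejections += little_mcar_test(x).p_value < 0.05
        assert rejections / reps > 0.8
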