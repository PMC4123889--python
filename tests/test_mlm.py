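import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

import spfmlm as sf
from spfmlm.mlm import DataError, MLMSpec, area_mean_residuals, fit_mlm


def make_data(ind, nbh=None):
    if nbh is None:
        nbh = pd.DataFrame({"area_id": sorted(ind["area_id"].unique())})
    return sf.TwoLevelData(ind, nbh)


class TestTwoLevelData:
    def test_orphan_area_rejected(self):
        ind = pd.DataFrame({"area_id": ["a", "a", "b", "b"], "outcome": [1.0, 2, 3, 4]})
        nbh = pd.DataFrame({"area_id": ["a"]})
        with pytest.raises(DataError, match="unknown areas"):
            sf.TwoLevelData(ind, nbh)

    def test_single_area_rejected(self):
        ind = pd.DataFrame({"area_id": ["a", "a"], "outcome": [1.0, 2.0]})
        with pytest.raises(DataError, match="at least 2 areas"):
            make_data(ind)

    def test_thin_area_rejected(self):
        ind = pd.DataFrame({"area_id": ["a", "a", "b"], "outcome": [1.0, 2, 3]})
        with pytest.raises(DataError, match="fewer than 2"):
            make_data(ind)

    def test_listwise_deletion_of_missing(self):
        ind = pd.DataFrame(
            {
                "area_id": ["a", "a", "a", "b", "b", "b"],
                "outcome": [1.0, np.nan, 2.0, 3.0, 4.0, 5.0],
                "x": [0.0, 1.0, 1.0, np.nan, 0.0, 1.0],
            }
        )
        nbh = pd.DataFrame({"area_id": ["a", "b"]})
        data = sf.TwoLevelData.from_frames(ind, nbh, used_columns=["x"])
        assert data.n_individuals == 4

    def test_csv_round_trip(self, tmp_path):
        ind = pd.DataFrame(
            {"area_id": ["a"] * 3 + ["b"] * 3, "outcome": np.arange(6.0), "x": np.ones(6)}
        )
        nbh = pd.DataFrame({"area_id": ["a", "b"], "z": [0.5, -0.5]})
        ind.to_csv(tmp_path / "ind.csv", index=False)
        nbh.to_csv(tmp_path / "nbh.csv", index=False)
        data = sf.TwoLevelData.from_csv(tmp_path / "ind.csv", tmp_path / "nbh.csv")
        assert data.n_areas == 2
        assert "z" in data.merged().columns


class TestSpecValidation:
    def test_random_slope_must_be_fixed_individual(self):
        with pytest.raises(ValueError, match="random_slope"):
            MLMSpec(fixed_individual=("a",), random_slope="b")

    def test_eigen_columns_disjoint(self):
        with pytest.raises(ValueError, match="overlap"):
            MLMSpec(fixed_individual=("a",), eigen_columns=("a",))

    def test_estimation_mode_checked(self):
        with pytest.raises(ValueError, match="estimation"):
            MLMSpec(estimation="MAP")


class TestFit:
    def test_null_model_parameter_recovery(self, balanced_two_level):
        data, truth = balanced_two_level
        fit = fit_mlm(data, MLMSpec())
        assert fit.var_intercept == pytest.approx(truth["tau00"], rel=0.15)
        assert fit.var_individual == pytest.approx(truth["sigma2"], rel=0.15)
        assert fit.gamma.loc["Intercept", "estimate"] == pytest.approx(truth["mu"], rel=0.05)

    def test_no_between_area_variance_hits_boundary(self):
        rng = np.random.default_rng(3)
        ind = pd.DataFrame(
            {
                "area_id": np.repeat([f"a{k}" for k in range(30)], 20),
                "outcome": rng.normal(0, 1, 600),
            }
        )
        fit = fit_mlm(make_data(ind), MLMSpec())
        assert fit.var_intercept < 0.05 * fit.var_individual
        # complete shrinkage: modes collapse toward zero with tau00
        modes = sf.conditional_modes(fit)
        assert np.max(np.abs(modes)) < 0.5

    def test_tiny_fit_matches_mvn_likelihood_oracle(self):
        rng = np.random.default_rng(7)
        y = rng.normal(5, 1, 6) + np.repeat(rng.normal(0, 1, 3), 2)
        ind = pd.DataFrame({"area_id": np.repeat(["a", "b", "c"], 2), "outcome": y})
        fit = fit_mlm(make_data(ind), MLMSpec())
        cov = fit.var_individual * np.eye(6)
        for g in range(3):
            cov[2 * g : 2 * g + 2, 2 * g : 2 * g + 2] += fit.var_intercept
        mu = fit.gamma.loc["Intercept", "estimate"]
        oracle = multivariate_normal.logpdf(y, mean=np.full(6, mu), cov=cov)
        assert fit.loglik == pytest.approx(oracle, abs=1e-6)

    def test_aic_recomputes_from_loglik(self, balanced_two_level):
        data, _ = balanced_two_level
        fit = fit_mlm(data, MLMSpec())
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.n_params)
        assert fit.n_params == 3  # intercept + tau00 + sigma2

    def test_collinear_design_rejected(self):
        rng = np.random.default_rng(1)
        ind = pd.DataFrame(
            {
                "area_id": np.repeat(["a", "b", "c"], 10),
                "outcome": rng.normal(size=30),
                "x1": np.tile(np.arange(10.0), 3),
            }
        )
        ind["x2"] = 2 * ind["x1"]
        with pytest.raises(DataError, match="collinear"):
            fit_mlm(make_data(ind), MLMSpec(fixed_individual=("x1", "x2")))

    def test_random_slope_variance_recovered(self):
        rng = np.random.default_rng(10)
        j, n = 150, 40
        ids = [f"a{k:03d}" for k in range(j)]
        x = rng.normal(0, 1, j * n)
        u0 = rng.normal(0, 1.0, j)
        u1 = rng.normal(0, 0.7, j)  # tau11 = 0.49
        y = 1.0 + 0.5 * x + np.repeat(u0, n) + np.repeat(u1, n) * x + rng.normal(0, 1.5, j * n)
        ind = pd.DataFrame({"area_id": np.repeat(ids, n), "outcome": y, "x": x})
        fit = fit_mlm(make_data(ind), MLMSpec(fixed_individual=("x",), random_slope="x"))
        assert fit.var_slope == pytest.approx(0.49, rel=0.3)
        assert fit.var_intercept == pytest.approx(1.0, rel=0.3)
        assert fit.n_params == 2 + 3


class TestICC:
    def test_published_variance_partition(self):
        # between 1591, within 66725 -> 0.023 to three decimals
        assert sf.icc_from_variances(1591.0, 66725.0) == pytest.approx(0.023, abs=5e-4)

    def test_zero_between_variance(self):
        assert sf.icc_from_variances(0.0, 10.0) == 0.0

    def test_equal_variances(self):
        assert sf.icc_from_variances(3.0, 3.0) == 0.5

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            sf.icc_from_variances(0.0, 0.0)

    def test_requires_null_fit(self, balanced_two_level):
        data, _ = balanced_two_level
        ind = data.individuals.assign(x=np.random.default_rng(0).normal(size=data.n_individuals))
        fit = fit_mlm(
            sf.TwoLevelData(ind, data.neighborhoods), MLMSpec(fixed_individual=("x",))
        )
        with pytest.raises(ValueError, match="null"):
            sf.icc(fit)

    def test_scale_invariance(self, balanced_two_level):
        data, _ = balanced_two_level
        base = sf.icc(fit_mlm(data, MLMSpec()))
        scaled = sf.TwoLevelData(
            data.individuals.assign(outcome=5.0 * data.individuals["outcome"]),
            data.neighborhoods,
        )
        assert sf.icc(fit_mlm(scaled, MLMSpec())) == pytest.approx(base, rel=1e-3)


class TestConditionalModes:
    def test_matches_shrinkage_formula_on_balanced_data(self, balanced_two_level):
        data, truth = balanced_two_level
        fit = fit_mlm(data, MLMSpec())
        n = truth["n_per_area"]
        t, s = fit.var_intercept, fit.var_individual
        ybar = data.individuals.groupby("area_id")["outcome"].mean().sort_index().to_numpy()
        mu = fit.gamma.loc["Intercept", "estimate"]
        blup = t / (t + s / n) * (ybar - mu)
        assert np.allclose(sf.conditional_modes(fit), blup, atol=1e-6)

    def test_shift_invariance(self, balanced_two_level):
        data, _ = balanced_two_level
        m1 = sf.conditional_modes(fit_mlm(data, MLMSpec()))
        shifted = sf.TwoLevelData(
            data.individuals.assign(outcome=data.individuals["outcome"] + 100.0),
            data.neighborhoods,
        )
        m2 = sf.conditional_modes(fit_mlm(shifted, MLMSpec()))
        assert np.allclose(m1, m2, atol=1e-5)

    def test_unknown_area_in_ordering_rejected(self, balanced_two_level):
        data, _ = balanced_two_level
        fit = fit_mlm(data, MLMSpec())
        with pytest.raises(KeyError):
            sf.conditional_modes(fit, ["zzz"])

    def test_area_mean_residuals_alternative(self, balanced_two_level):
        data, _ = balanced_two_level
        fit = fit_mlm(data, MLMSpec())
        raw = area_mean_residuals(fit)
        mu = fit.gamma.loc["Intercept", "estimate"]
        ybar = data.individuals.groupby("area_id")["outcome"].mean().sort_index().to_numpy()
        assert np.allclose(raw, ybar - mu, atol=1e-8)


@pytest.fixture(scope="module")
def covariate_data():
    rng = np.random.default_rng(21)
    j, n = 40, 25
    ids = [f"a{k:02d}" for k in range(j)]
    x = rng.binomial(1, 0.5, j * n).astype(float)
    u0 = rng.normal(0, 0.8, j)
    y = 2.0 + 3.0 * x + np.repeat(u0, n) + rng.normal(0, 1.0, j * n)
    ind = pd.DataFrame({"area_id": np.repeat(ids, n), "outcome": y, "x": x})
    return make_data(ind)


class TestCompareFits:

    def test_nested_ml_loglik_monotone(self, covariate_data):
        f0 = fit_mlm(covariate_data, MLMSpec())
        f1 = fit_mlm(covariate_data, MLMSpec(fixed_individual=("x",)))
        assert f1.loglik >= f0.loglik

    def test_identical_fits_zero_aic_difference(self, covariate_data):
        f0 = fit_mlm(covariate_data, MLMSpec())
        table = sf.compare_fits({"a": f0, "b": f0})
        assert table.loc["a", "aic"] == table.loc["b", "aic"]

    def test_planted_effect_reduces_individual_variance(self, covariate_data):
        f0 = fit_mlm(covariate_data, MLMSpec())
        f1 = fit_mlm(covariate_data, MLMSpec(fixed_individual=("x",)))
        table = sf.compare_fits({"null": f0, "level1": f1}, baseline="null")
        assert table.loc["level1", "prop_reduction_individual"] > 0

    def test_reml_with_different_fixed_effects_refused(self, covariate_data):
        f0 = fit_mlm(covariate_data, MLMSpec(estimation="REML"))
        f1 = fit_mlm(covariate_data, MLMSpec(fixed_individual=("x",), estimation="REML"))
        with pytest.raises(ValueError, match="not comparable"):
            sf.compare_fits({"a": f0, "b": f1})


class TestParameterRecoveryProperty:
    def test_gamma_means_within_two_mc_ses(self):
        """Across replicates the fixed-effect estimators are unbiased."""
        cfg_template = dict(
            rows=5,
            cols=8,
            n_per_area=12,
            spatial_signal=None,
        )
        estimates: dict[str, list[float]] = {}
        truth = {"Intercept": 785.31, **sf.synthdata.DEFAULT_GAMMA_IND, **sf.synthdata.DEFAULT_GAMMA_NBH}
        for seed in range(20):
            data, _ = sf.simulate(sf.SyntheticConfig(**cfg_template, seed=seed))
            fit = fit_mlm(
                data,
                MLMSpec(
                    fixed_individual=("female", "income", "unemployed", "low_stress"),
                    fixed_neighborhood=("deprivation", "doctors_per_1000", "lgfi"),
                    random_slope="income",
                ),
            )
            for name in truth:
                estimates.setdefault(name, []).append(float(fit.gamma.loc[name, "estimate"]))
        # the 8 estimators are strongly correlated (intercept vs area
        # covariates), so per-parameter SE bounds misfire; test the joint
        # zero-bias hypothesis with Hotelling's T^2 at the 1% level
        from scipy.stats import f as f_dist

        names = list(truth)
        e = np.column_stack([estimates[n] for n in names])
        n_rep, p = e.shape
        diff = e.mean(axis=0) - np.array([truth[n] for n in names])
        cov = np.cov(e, rowvar=False)
        t2 = n_rep * diff @ np.linalg.solve(cov, diff)
        f_stat = t2 * (n_rep - p) / (p * (n_rep - 1))
        assert f_stat < f_dist.ppf(0.99, p, n_rep - p)
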