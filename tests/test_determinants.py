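"""Survey-weighted logistic regression, variable selection and imputation."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from claimsagree.determinants import (
    SeparationError,
    agreement_outcome,
    build_design,
    fit_weighted_logistic,
    impute_and_pool,
    impute_categoricals,
    purposeful_selection,
    rubin_pool,
    univariable_pvalue,
)


def simulate(rng, n=1000, beta=(-0.5, np.log(2.0))):
    x = rng.integers(0, 2, n).astype(float)
    y = (rng.random(n) < expit(beta[0] + beta[1] * x)).astype(float)
    X = np.column_stack([np.ones(n), x])
    return X, x, y


class TestAgreementOutcome:
    def test_concordance_mapping(self):
        out = agreement_outcome([True, True, False, False], [True, False, True, False])
        assert out.tolist() == [True, False, False, True]

    def test_missing_self_report_excluded(self):
        out = agreement_outcome([True, False], pd.array([pd.NA, False], dtype="boolean"))
        assert out.isna().tolist() == [True, False]


class TestWeightedLogistic:
    def test_intercept_only_closed_form(self, rng):
        y = (rng.random(500) < 0.3).astype(float)
        w = rng.uniform(1, 30, 500)
        fit = fit_weighted_logistic(np.ones((500, 1)), y, w, columns=["Intercept"])
        expected = logit(np.sum(w * y) / np.sum(w))
        assert fit.params["Intercept"] == pytest.approx(expected, abs=1e-8)

    def test_matches_statsmodels_beta_with_weights(self, rng):
        import statsmodels.api as sm

        X, _, y = simulate(rng)
        w = rng.uniform(0.5, 40, len(y))
        fit = fit_weighted_logistic(X, y, w)
        glm = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w).fit()
        np.testing.assert_allclose(fit.params.to_numpy(), glm.params, atol=1e-7)

    def test_unit_weight_sandwich_matches_statsmodels_hc0(self, rng):
        import statsmodels.api as sm

        X, _, y = simulate(rng)
        fit = fit_weighted_logistic(X, y)
        sm_fit = sm.Logit(y, X).fit(disp=0, cov_type="HC0")
        np.testing.assert_allclose(fit.params.to_numpy(), sm_fit.params, atol=1e-6)
        np.testing.assert_allclose(
            fit.cov.to_numpy(), sm_fit.cov_params(), rtol=1e-4
        )

    def test_weight_scale_invariance(self, rng):
        X, _, y = simulate(rng)
        w = rng.uniform(1, 10, len(y))
        f1 = fit_weighted_logistic(X, y, w)
        f2 = fit_weighted_logistic(X, y, 17.0 * w)
        np.testing.assert_allclose(f1.params, f2.params, atol=1e-7)

    def test_or_recovery_single_run(self, rng):
        X, _, y = simulate(rng, n=4000)
        fit = fit_weighted_logistic(X, y, columns=["Intercept", "x"])
        assert np.exp(fit.params["x"]) == pytest.approx(2.0, abs=0.35)
        assert (np.diag(fit.cov) >= 0).all()

    def test_separation_raises(self):
        X = np.column_stack([np.ones(20), np.r_[np.zeros(10), np.ones(10)]])
        y = np.r_[np.zeros(10), np.ones(10)]
        with pytest.raises(SeparationError):
            fit_weighted_logistic(X, y, columns=["Intercept", "x"])

    def test_rank_deficiency_names_aliased_column(self):
        X = np.column_stack([np.ones(30), np.arange(30.0), 2 * np.arange(30.0)])
        y = (np.arange(30) % 2).astype(float)
        with pytest.raises(np.linalg.LinAlgError, match="aliased"):
            fit_weighted_logistic(X, y, columns=["Intercept", "x", "x2"])


class TestBuildDesign:
    def test_reference_level_dropped(self):
        data = pd.DataFrame({"v": ["a", "b", "c", "a"]})
        dm = build_design(data, ["v"], {"v": "a"})
        assert dm.columns == ["Intercept", "v[b]", "v[c]"]
        assert dm.terms["v"] == [1, 2]

    def test_missing_values_rejected(self):
        data = pd.DataFrame({"v": ["a", None]})
        with pytest.raises(ValueError, match="missing"):
            build_design(data, ["v"])


class TestPurposefulSelection:
    def test_strong_covariate_retained_nulls_dropped(self):
        rng = np.random.default_rng(7)
        n = 1500
        data = pd.DataFrame(
            {f"x{j}": rng.integers(0, 2, n).astype(str) for j in range(6)}
        )
        strong = (data["x0"] == "1").to_numpy(float)
        y = pd.Series(rng.random(n) < expit(-0.5 + 1.3 * strong), dtype=object)
        trace, final = purposeful_selection(list(data.columns), data, y)
        assert "x0" in trace.entered and "x0" in trace.retained
        assert trace.univariable_p["x0"] < 0.25
        assert "x0" in final.terms

    def test_no_candidate_passing_gives_intercept_only(self):
        rng = np.random.default_rng(8)
        data = pd.DataFrame({"v": np.repeat(["a", "b"], 200)})
        y = pd.Series(rng.random(400) < 0.5, dtype=object)
        p = univariable_pvalue(data, "v", y)
        trace, final = purposeful_selection(["v"], data, y, threshold=min(p / 2, 0.01))
        assert trace.entered == []
        assert list(final.params.index) == ["Intercept"]


class TestImputationAndPooling:
    def test_no_missing_pooled_equals_single_fit(self, rng):
        n = 600
        data = pd.DataFrame({"v": rng.choice(["a", "b", "c"], n)})
        y = pd.Series(rng.random(n) < 0.4, dtype=object)
        w = pd.Series(rng.uniform(1, 20, n))
        pooled = impute_and_pool(data, ["v"], y, w, m=5, seed=1, reference={"v": "a"})
        dm = build_design(data, ["v"], {"v": "a"})
        single = fit_weighted_logistic(dm, y.astype(float), w)
        np.testing.assert_allclose(pooled.params, single.params, atol=1e-10)
        np.testing.assert_allclose(pooled.cov, single.cov, atol=1e-10)

    def test_m_equals_one_is_that_imputation(self, rng):
        fit = fit_weighted_logistic(
            np.ones((50, 1)), (rng.random(50) < 0.5).astype(float), columns=["Intercept"]
        )
        pooled = rubin_pool([fit])
        np.testing.assert_allclose(pooled.cov, fit.cov)

    def test_pooled_variance_at_least_within_mean(self, rng):
        n = 500
        data = pd.DataFrame({"v": rng.choice(["a", "b"], n).astype(object)})
        data.loc[rng.random(n) < 0.2, "v"] = None
        y = pd.Series(rng.random(n) < expit((data["v"] == "b").fillna(False) * 0.8 - 0.4), dtype=object)
        fits = []
        g = np.random.default_rng(3)
        for _ in range(8):
            completed = impute_categoricals(data, ["v"], y, rng=g)
            dm = build_design(completed, ["v"], {"v": "a"})
            fits.append(fit_weighted_logistic(dm, y.astype(float)))
        pooled = rubin_pool(fits)
        within = np.stack([np.diag(f.cov) for f in fits]).mean(axis=0)
        assert (np.diag(pooled.cov) >= within - 1e-12).all()

    def test_fully_missing_variable_errors(self):
        data = pd.DataFrame({"v": [None, None]})
        y = pd.Series([True, False], dtype=object)
        with pytest.raises(ValueError, match="100% missing"):
            impute_categoricals(data, ["v"], y, rng=np.random.default_rng(0))

    def test_imputed_values_come_from_observed_levels(self, rng):
        n = 300
        data = pd.DataFrame({"v": rng.choice(["a", "b"], n).astype(object)})
        data.loc[rng.random(n) < 0.3, "v"] = None
        y = pd.Series(rng.random(n) < 0.5, dtype=object)
        completed = impute_categoricals(data, ["v"], y, rng=rng)
        assert completed["v"].notna().all()
        assert set(completed["v"].unique()) <= {"a", "b"}


def test_mcar_imputation_unbiased_small_study():
    """10% MCAR missingness in one binary covariate: the Rubin-pooled log-OR
    stays near the truth and its CI covers it most of the time."""
    true_beta = np.log(2.0)
    hits, betas = 0, []
    for s in range(30):
        rng = np.random.default_rng(500 + s)
        n = 1200
        x = rng.integers(0, 2, n)
        y = pd.Series(rng.random(n) < expit(-0.4 + true_beta * x), dtype=object)
        data = pd.DataFrame({"v": np.where(x == 1, "b", "a").astype(object)})
        data.loc[rng.random(n) < 0.10, "v"] = None
        pooled = impute_and_pool(data, ["v"], y, m=10, seed=s, reference={"v": "a"})
        b = pooled.params["v[b]"]
        se = np.sqrt(pooled.cov.loc["v[b]", "v[b]"])
        betas.append(b)
        hits += abs(b - true_beta) < 1.96 * se
    assert np.mean(betas) == pytest.approx(true_beta, abs=0.12)
    assert hits >= 24  # ~95% nominal coverage, small-sample slack
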