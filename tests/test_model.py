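import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cqtc.model as model_mod
from cqtc.errors import ConvergenceFailure, DesignMatrixError, ModelFitError, RankError
from cqtc.model import (ModelSpec, beta_at_variance, build_design, fit_ml,
                        fit_with_ladder, slope_summaries)
from tests.conftest import random_small_dataset


def mvn_loglik(X, Z, y, groups, beta, G, sigma2):
    """Independent oracle: per-subject multivariate-normal density with
    V = Z G Z' + sigma^2 I, evaluated directly via scipy."""
    total = 0.0
    for g in np.unique(groups):
        m = groups == g
        V = sigma2 * np.eye(m.sum())
        if G.size:
            V = V + Z[m] @ G @ Z[m].T
        total += stats.multivariate_normal.logpdf(y[m], mean=X[m] @ beta, cov=V)
    return total


def _obs(rows):
    cols = ["subject_id", "period", "day", "nominal_time_h", "day7", "trt",
            "dqtcf_ms", "baseline_dev_ms", "cp_parent", "cp_metabolite"]
    return pd.DataFrame(rows, columns=cols)


class TestBuildDesign:
    def test_reference_level_row(self):
        obs = _obs([("A", 1, 1, 0.0, 0, 0, 0.0, 2.0, 0.0, 0.0)])
        d = build_design(obs, ModelSpec("parent"), include_day1_predose=True)
        np.testing.assert_array_equal(
            d.X[0], [1, 0, 0, 2, 0, 0, 0, 0, 0, 0, 0])
        assert len(d.fe_names) == 11

    def test_active_day7_row_coding(self):
        obs = _obs([("A", 1, 7, 2.0, 1, 1, 5.0, 0.0, 1.0, 0.5)])
        d = build_design(obs, ModelSpec("parent"))
        names = d.fe_names
        row = dict(zip(names, d.X[0]))
        assert row["intercept"] == 1 and row["trt"] == 1 and row["day7"] == 1
        assert row["ntime_2"] == 1 and sum(row[f"ntime_{t:g}"] for t in
                                           (1, 4, 8, 24)) == 0
        assert row["cp_parent"] == 1.0 and row["day7_cp_parent"] == 1.0

    def test_parent_metabolite_has_13_columns(self):
        obs = _obs([("A", 1, 1, 2.0, 0, 1, 5.0, 0.0, 1.0, 0.5)])
        d = build_design(obs, ModelSpec("parent_metabolite"))
        assert len(d.fe_names) == 13
        assert d.Z.shape[1] == 3

    def test_missing_metabolite_on_active_row_rejected(self):
        obs = _obs([("A", 1, 1, 2.0, 0, 1, 5.0, 0.0, 1.0, np.nan)])
        with pytest.raises(DesignMatrixError, match="metabolite"):
            build_design(obs, ModelSpec("parent_metabolite"))

    def test_unseen_time_level_rejected(self):
        obs = _obs([("A", 1, 1, 3.0, 0, 1, 5.0, 0.0, 1.0, 0.5)])
        with pytest.raises(DesignMatrixError, match="nominal-time"):
            build_design(obs, ModelSpec("parent"))

    def test_day1_predose_rows_dropped_by_default(self):
        obs = _obs([("A", 1, 1, 0.0, 0, 1, 0.0, 0.0, 0.0, 0.0),
                    ("A", 1, 1, 2.0, 0, 1, 5.0, 0.0, 1.0, 0.0)])
        obs["predose_day1"] = [True, False]
        d = build_design(obs, ModelSpec("parent"))
        assert d.X.shape[0] == 1


class TestFitMl:
    def test_noise_free_recovery_to_1e8(self):
        rng = np.random.default_rng(5)
        n, p = 60, 4
        X = np.column_stack([np.ones(n), rng.normal(0, 1, (n, p - 1))])
        Z = np.column_stack([np.ones(n), rng.uniform(0, 2, n)])
        groups = np.repeat(np.arange(6), 10)
        beta = np.array([1.0, -2.0, 0.5, 3.0])
        y = X @ beta  # zero random effects, zero noise
        fit = fit_ml(X, Z, y, groups, "unstructured")
        np.testing.assert_allclose(fit.beta, beta, atol=1e-8)
        assert fit.sigma2 <= 1e-6  # driven to the variance floor

    def test_gls_reduces_to_ols_at_zero_G(self):
        rng = np.random.default_rng(6)
        X, Z, y, groups = random_small_dataset(rng)
        b_gls = beta_at_variance(X, Z, y, groups, np.zeros((2, 2)), 1.3)
        b_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(b_gls, b_ols, atol=1e-10)

    def test_ml_sigma2_is_biased_downward_vs_ols(self):
        # with no random effects, ML residual variance is RSS/n, i.e. the
        # (n-p)/n multiple of the unbiased OLS estimate - the ML signature
        rng = np.random.default_rng(7)
        n, p = 24, 3
        X = np.column_stack([np.ones(n), rng.normal(0, 1, (n, p - 1))])
        y = X @ np.array([1.0, 0.5, -0.5]) + rng.normal(0, 1, n)
        Z = np.ones((n, 1))
        fit = fit_ml(X, Z, y, np.repeat(np.arange(4), 6), "none")
        rss = np.sum((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2)
        s2_ols = rss / (n - p)
        assert fit.sigma2 == pytest.approx((n - p) / n * s2_ols, rel=1e-10)
        assert fit.sigma2 < s2_ols

    def test_duplicated_column_rejected_not_absorbed(self):
        rng = np.random.default_rng(8)
        X, Z, y, groups = random_small_dataset(rng)
        X2 = np.column_stack([X, X[:, 1]])
        with pytest.raises(RankError):
            fit_ml(X2, Z, y, groups)

    def test_loglik_matches_direct_mvn_oracle(self):
        rng = np.random.default_rng(9)
        X, Z, y, groups = random_small_dataset(rng)
        try:
            fit = fit_ml(X, Z, y, groups, "unstructured")
        except ConvergenceFailure as exc:
            fit = exc.best
        direct = mvn_loglik(X, Z, y, groups, fit.beta, fit.re_cov, fit.sigma2)
        assert fit.loglik == pytest.approx(direct, abs=1e-6)

    def test_convergence_failure_carries_best_iterate(self, monkeypatch):
        rng = np.random.default_rng(10)
        X, Z, y, groups = random_small_dataset(rng)
        # force the optimizer to report failure on every try
        import scipy.optimize as so
        real = so.minimize

        def bad(*a, **k):
            res = real(*a, **k)
            res.success = False
            res.message = "stubbed failure"
            return res
        monkeypatch.setattr(model_mod.optimize, "minimize", bad)
        with pytest.raises(ConvergenceFailure) as exc:
            fit_ml(X, Z, y, groups, "unstructured", max_restarts=1)
        assert exc.value.best is not None
        assert np.isfinite(exc.value.best.loglik)


class TestStatsmodelsCrossCheck:
    def test_parent_model_agrees_with_mixedlm(self, matched):
        """Independent route: statsmodels MixedLM (ML, random intercept +
        slope, unstructured) on the same design matrices."""
        import statsmodels.regression.mixed_linear_model as mlm
        m, _ = matched
        spec = ModelSpec("parent")
        d = build_design(m, spec)
        fit = fit_ml(d.X, d.Z, d.y, d.groups, "unstructured",
                     fe_names=d.fe_names, re_names=d.re_names)
        sm_fit = mlm.MixedLM(d.y, d.X, groups=d.groups, exog_re=d.Z).fit(
            reml=False, method=["lbfgs"], maxiter=500)
        # same maximum: neither implementation should beat the other
        assert fit.loglik == pytest.approx(sm_fit.llf, abs=1e-4)
        np.testing.assert_allclose(fit.beta, sm_fit.fe_params, atol=1e-3)
        slope_i = d.fe_names.index("cp_parent")
        assert fit.beta_cov[slope_i, slope_i] == pytest.approx(
            sm_fit.cov_params()[slope_i, slope_i], rel=0.05)


class TestLadder:
    def test_well_conditioned_data_stays_unstructured(self, matched):
        m, _ = matched
        fit = fit_with_ladder(m, ModelSpec("parent"))
        assert fit.structure_used == "unstructured"
        assert fit.converged
        assert fit.n_obs == (~m["predose_day1"]).sum()

    def test_demotion_on_unstructured_failure(self, matched, monkeypatch):
        m, _ = matched
        real = model_mod.fit_ml

        def flaky(X, Z, y, groups, re_structure="unstructured", **kw):
            if re_structure == "unstructured":
                raise ConvergenceFailure("stub: no convergence")
            return real(X, Z, y, groups, re_structure, **kw)
        monkeypatch.setattr(model_mod, "fit_ml", flaky)
        fit = model_mod.fit_with_ladder(m, ModelSpec("parent"))
        assert fit.structure_used == "diagonal"
        assert fit.attempts[0][0] == "unstructured"

    def test_all_rungs_fail_is_terminal(self, matched, monkeypatch):
        m, _ = matched

        def dead(*a, **k):
            raise ConvergenceFailure("stub")
        monkeypatch.setattr(model_mod, "fit_ml", dead)
        with pytest.raises(ModelFitError):
            model_mod.fit_with_ladder(m, ModelSpec("parent"))


class TestSlopeSummaries:
    def test_scalar_contrast_hand_arithmetic(self, matched):
        m, _ = matched
        fit = fit_with_ladder(m, ModelSpec("parent"), df_method="residual")
        s1 = next(s for s in slope_summaries(fit, ModelSpec("parent"),
                                             df_method="residual")
                  if s.day == 1)
        i = fit.fe_names.index("cp_parent")
        tcrit = stats.t.ppf(0.975, fit.residual_df)
        se = np.sqrt(fit.beta_cov[i, i])
        assert s1.estimate == pytest.approx(fit.beta[i])
        assert s1.ci_high == pytest.approx(fit.beta[i] + tcrit * se)

    def test_day7_slope_is_sum_with_interaction(self, matched):
        m, _ = matched
        spec = ModelSpec("parent")
        fit = fit_with_ladder(m, spec)
        s = {x.day: x for x in slope_summaries(fit, spec)}
        i = fit.fe_names.index("cp_parent")
        j = fit.fe_names.index("day7_cp_parent")
        assert s[7].estimate == pytest.approx(fit.beta[i] + fit.beta[j])
        var7 = fit.beta_cov[i, i] + 2 * fit.beta_cov[i, j] + fit.beta_cov[j, j]
        assert s[7].se == pytest.approx(np.sqrt(var7))

    def test_interval_symmetric_about_estimate(self, matched):
        m, _ = matched
        spec = ModelSpec("parent")
        fit = fit_with_ladder(m, spec)
        for s in slope_summaries(fit, spec):
            assert (s.ci_low + s.ci_high) / 2 == pytest.approx(s.estimate)
            assert s.ci_low <= s.estimate <= s.ci_high
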