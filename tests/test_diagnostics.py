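import numpy as np
import pandas as pd
import pytest

from cqtc.diagnostics import (gof, heart_rate_effect, hysteresis_lag,
                              linearity_check, rr_adequacy)
from cqtc.errors import DiagnosticsError
from cqtc.model import ModelSpec, fit_with_ladder


def _ecg(rows):
    return pd.DataFrame(rows, columns=["subject_id", "period", "day",
                                       "nominal_time_h", "replicate",
                                       "hr_bpm"])


class TestHeartRateEffect:
    def test_constant_hr_gives_zero_cells(self):
        rows = [("A", 1, 1, t, 1, 60.0) for t in (0.0, 1.0, 2.0)]
        rows += [("B", 1, 1, t, 1, 64.0) for t in (0.0, 1.0, 2.0)]
        arm = pd.DataFrame({"subject_id": ["A", "B"], "period": [1, 1],
                            "treatment": ["active", "placebo"]})
        out = heart_rate_effect(_ecg(rows), arm)
        assert np.allclose(out.table["mean_dhr_bpm"], 0.0)
        assert out.max_abs_contrast == 0.0

    def test_single_active_bump_propagates_to_contrast(self):
        rows = [("A", 1, 1, t, 1, 60.0 + (5.0 if t == 2.0 else 0.0))
                for t in (0.0, 1.0, 2.0)]
        rows += [("B", 1, 1, t, 1, 64.0) for t in (0.0, 1.0, 2.0)]
        arm = pd.DataFrame({"subject_id": ["A", "B"], "period": [1, 1],
                            "treatment": ["active", "placebo"]})
        out = heart_rate_effect(_ecg(rows), arm)
        assert out.max_abs_contrast == pytest.approx(5.0)

    def test_missing_predose_baseline_logged(self):
        rows = [("A", 1, 1, 2.0, 1, 70.0)]  # no pre-dose record at all
        arm = pd.DataFrame({"subject_id": ["A"], "period": [1],
                            "treatment": ["active"]})
        out = heart_rate_effect(_ecg(rows), arm)
        assert len(out.exclusions) == 1

    def test_simulated_trial_contrast_within_noise_band(self, trial):
        """No HR drug effect in the generator: the max active-placebo
        contrast stays inside an analytic Monte-Carlo band."""
        out = heart_rate_effect(trial.ecg, trial.randomization)
        # per-cell SE: HR noise SD ~ sqrt(3^2 + 1.5^2) per replicate, ~30
        # subject-periods per arm-cell, 3 replicates; compare max of ~tens
        # of cells against 4x the cell-difference SE
        cell_se = np.sqrt(2) * np.sqrt(3.0 ** 2 + 1.5 ** 2) / np.sqrt(3 * 12)
        assert out.max_abs_contrast < 4 * cell_se * 2


class TestRrAdequacy:
    def test_fridericia_consistent_data_is_flat_at_n1000(self):
        rng = np.random.default_rng(0)
        rr = rng.uniform(0.7, 1.3, 1000)
        qtcf = 400 + rng.normal(0, 5, 1000)  # independent of RR
        out = rr_adequacy(pd.DataFrame({"qtcf_ms": qtcf, "rr_s": rr}))
        assert out.adequate
        assert abs(out.slope_ms_per_s) < 2.0

    def test_uncorrected_qt_shows_negative_slope(self):
        rng = np.random.default_rng(1)
        rr = rng.uniform(0.7, 1.3, 500)
        qtcf_of_constant_qt = 400.0 / np.cbrt(rr)
        out = rr_adequacy(pd.DataFrame({"qtcf_ms": qtcf_of_constant_qt,
                                        "rr_s": rr}))
        assert not out.adequate
        assert out.slope_ms_per_s < -50

    def test_two_points_rejected(self):
        with pytest.raises(DiagnosticsError):
            rr_adequacy(pd.DataFrame({"qtcf_ms": [400, 410], "rr_s": [0.9, 1.0]}))


def _obs(times, dq, conc, dose=540):
    return pd.DataFrame({
        "nominal_time_h": times, "dqtcf_ms": dq, "cp_parent": conc,
        "trt": 1, "dose_mg": dose})


class TestHysteresis:
    def test_direct_effect_has_zero_lag(self):
        times = [0.0, 1.0, 2.0, 4.0, 8.0]
        conc = [0.0, 2.0, 3.0, 2.5, 1.0]
        out = hysteresis_lag(_obs(times, [c * 2 for c in conc], conc))
        assert out[0].lag_h == 0.0 and not out[0].tie

    def test_shifted_effect_lag_is_grid_distance(self):
        times = [0.0, 1.0, 2.0, 4.0, 8.0]
        conc = [0.0, 2.0, 3.0, 2.5, 1.0]
        dq = [0.0, 0.5, 2.0, 3.0, 2.5]  # peak one grid step later
        out = hysteresis_lag(_obs(times, dq, conc))
        assert out[0].lag_h == pytest.approx(2.0)  # 4 h - 2 h

    def test_all_zero_effect_flags_tie(self):
        times = [0.0, 1.0, 2.0, 4.0]
        out = hysteresis_lag(_obs(times, [0.0] * 4, [0.0, 1.0, 2.0, 1.0]))
        assert out[0].tie

    def test_invariant_to_concentration_scaling(self):
        times = [0.0, 1.0, 2.0, 4.0, 8.0]
        conc = np.array([0.0, 2.0, 3.0, 2.5, 1.0])
        dq = [0.0, 1.0, 4.0, 3.0, 2.0]
        a = hysteresis_lag(_obs(times, dq, conc))
        b = hysteresis_lag(_obs(times, dq, conc * 1000))
        assert a[0].lag_h == b[0].lag_h

    def test_too_few_times_rejected(self):
        with pytest.raises(DiagnosticsError):
            hysteresis_lag(_obs([0.0, 2.0], [0.0, 1.0], [0.0, 1.0]))


class TestLinearity:
    def test_noise_free_linear_deviation_tiny(self):
        c = np.linspace(0, 4, 50)
        out = linearity_check(_obs(np.zeros(50), 2.0 - 0.5 * c, c))
        assert out.max_abs_deviation_ms < 1e-6

    def test_quadratic_curvature_detected_and_matches_direct_eval(self):
        from statsmodels.nonparametric.smoothers_lowess import lowess
        c = np.linspace(0, 4, 60)
        y = 1.0 + 0.5 * c + 0.8 * c ** 2
        out = linearity_check(_obs(np.zeros(60), y, c))
        sm = lowess(y, c, frac=0.75, return_sorted=True)
        line = np.polyval(np.polyfit(c, y, 1), sm[:, 0])
        lo, hi = np.quantile(c, [0.05, 0.95])
        inside = (sm[:, 0] >= lo) & (sm[:, 0] <= hi)
        expected = np.max(np.abs(sm[inside, 1] - line[inside]))
        assert out.max_abs_deviation_ms == pytest.approx(expected, rel=1e-9)
        assert out.max_abs_deviation_ms > 0.1

    def test_small_n_rejected(self):
        c = np.linspace(0, 4, 10)
        with pytest.raises(DiagnosticsError):
            linearity_check(_obs(np.zeros(10), c, c))


class TestGof:
    def test_well_specified_fit_residuals_centred(self, matched):
        m, _ = matched
        spec = ModelSpec("parent")
        fit = fit_with_ladder(m, spec)
        g = gof(fit, m, spec)
        # marginal residual means by time within analytic SE bands
        for _, row in g.by_time.iterrows():
            band = 4 * np.sqrt(fit.sigma2 + fit.re_cov[0, 0]) / np.sqrt(row["count"])
            assert abs(row["mean"]) < band
        assert abs(g.resid_mean) < 1.0
        assert g.obs_vs_pred_corr > 0.5

    def test_near_noise_free_self_fit(self):
        from cqtc.simulate import QtcTruth, TrialDesign, simulate_trial, analyze_trial
        truth = QtcTruth(re_sd=(0.0, 0.0, 0.0), sigma=1e-3, triplicate_sd=0.0,
                         baseline_period_sd=0.0)
        trial = simulate_trial(TrialDesign.default(), qtc_truth=truth, seed=3)
        fit, _, _, m = analyze_trial(trial)
        g = gof(fit, m, ModelSpec("parent"))
        # only integer-rounding noise remains
        assert abs(g.resid_mean) < 0.2
        assert g.obs_vs_pred_corr > 0.99

    def test_omitting_time_terms_leaves_time_trend(self, matched):
        """Deliberate misspecification: dropping the circadian (nominal-time)
        coefficients leaves a detectable residual pattern by time."""
        import dataclasses
        m, _ = matched
        spec = ModelSpec("parent")
        fit = fit_with_ladder(m, spec)
        g_good = gof(fit, m, spec)
        beta = fit.beta.copy()
        for i, name in enumerate(fit.fe_names):
            if name.startswith("ntime_"):
                beta[i] = 0.0
        broken = dataclasses.replace(fit, beta=beta)
        g_bad = gof(broken, m, spec)
        spread_good = g_good.by_time["mean"].abs().max()
        spread_bad = g_bad.by_time["mean"].abs().max()
        assert spread_good < 1.0
        assert spread_bad > 2 * spread_good
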