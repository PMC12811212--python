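import numpy as np
import pandas as pd
import pytest

from cqtc.ecg import fridericia_qtc
from cqtc.simulate import (PanelDesign, PkTruth, QtcTruth, TrialDesign,
                           _single_dose_unit, recovery_study, simulate_pk,
                           simulate_trial)


@pytest.fixture(scope="module")
def pk_truth():
    return PkTruth()


class TestPkModel:
    def test_single_dose_starts_at_zero(self, pk_truth):
        assert _single_dose_unit(np.array([0.0]), pk_truth.ka_per_h,
                                 pk_truth.lambda1_per_h,
                                 pk_truth.lambda2_per_h,
                                 pk_truth.frac_fast)[0] == 0.0

    def test_tmax_in_design_window(self, pk_truth):
        t = np.linspace(0, 24, 4801)
        c = _single_dose_unit(t, pk_truth.ka_per_h, pk_truth.lambda1_per_h,
                              pk_truth.lambda2_per_h, pk_truth.frac_fast)
        tmax = t[np.argmax(c)]
        assert 1.5 <= tmax <= 4.0

    def test_terminal_half_life_matches_configuration(self, pk_truth):
        t = np.linspace(24, 48, 200)
        c = _single_dose_unit(t, pk_truth.ka_per_h, pk_truth.lambda1_per_h,
                              pk_truth.lambda2_per_h, pk_truth.frac_fast)
        slope = np.polyfit(t, np.log(c), 1)[0]
        assert np.log(2) / -slope == pytest.approx(pk_truth.half_life_h,
                                                   rel=0.05)

    def test_rate_collision_uses_limit_formula(self):
        # ka equal to an elimination rate must yield a finite curve
        t = np.linspace(0, 24, 100)
        c = _single_dose_unit(t, 0.3, 0.3, 0.072, 0.75)
        assert np.all(np.isfinite(c)) and c.max() > 0

    def test_steady_state_cmax_calibrated_to_therapeutic(self, pk_truth):
        from cqtc.simulate import _superpose
        grid = np.linspace(144, 168, 2401)
        css = _superpose(grid, 45.0, 7, pk_truth.ka_per_h,
                         pk_truth.lambda1_per_h, pk_truth.lambda2_per_h,
                         pk_truth.frac_fast, pk_truth.scale_per_mg)
        assert css.max() == pytest.approx(0.375, rel=1e-6)


class TestSimulatePk:
    def test_noise_free_dose_proportionality_exact(self):
        design = TrialDesign(panels=(PanelDesign("A", 1, (300, 600),
                                                 n_subjects=4, n_active=4),))
        pk = simulate_pk(design, PkTruth(), seed=5, noise_free=True)
        par = pk[pk["analyte"] == "parent"]
        wide = par.pivot_table(index=["subject_id", "nominal_time_h"],
                               columns="period", values="concentration")
        post = wide[wide[1] > 0]
        np.testing.assert_allclose(post[2] / post[1], 2.0, rtol=1e-9)

    def test_blq_and_predose_zeroed(self, trial):
        pk = trial.pk
        assert (pk.loc[pk["blq"], "concentration"] == 0).all()
        pre = pk[(pk["day"] == 1) & (pk["nominal_time_h"] == 0)]
        assert (pre["concentration"] == 0).all()

    def test_metabolite_only_in_parts_1_and_2(self, trial):
        met = trial.pk[trial.pk["analyte"] == "metabolite"]
        assert set(met["part"]) == {1, 2}


class TestTrialStructure:
    def test_randomization_6_to_2_exact_per_panel_period(self, trial):
        counts = (trial.randomization.groupby(["panel", "period", "treatment"])
                  ["subject_id"].count().unstack())
        assert (counts["active"] == 6).all()
        assert (counts["placebo"] == 2).all()

    def test_ecg_row_count_matches_closed_form(self, trial):
        design = TrialDesign.default()
        assert len(trial.ecg) == design.expected_ecg_rows()
        # Part 3: 8 subjects x 2 periods x 6 times x 3 replicates
        part3 = trial.ecg[trial.ecg["part"] == 3]
        assert len(part3) == 8 * 2 * 6 * 3

    def test_same_seed_byte_identical(self):
        design = TrialDesign(panels=(PanelDesign("E", 3, (720,),
                                                 n_subjects=4, n_active=3),))
        a = simulate_trial(design, seed=9)
        b = simulate_trial(design, seed=9)
        assert a.ecg.to_csv(index=False) == b.ecg.to_csv(index=False)
        assert a.pk.to_csv(index=False) == b.pk.to_csv(index=False)
        assert (a.randomization.to_csv(index=False)
                == b.randomization.to_csv(index=False))

    def test_different_seed_differs(self):
        design = TrialDesign(panels=(PanelDesign("E", 3, (720,),
                                                 n_subjects=4, n_active=3),))
        a = simulate_trial(design, seed=9)
        b = simulate_trial(design, seed=10)
        assert a.ecg.to_csv(index=False) != b.ecg.to_csv(index=False)

    def test_fridericia_round_trip_identity(self, trial):
        # QT was back-computed from QTcF and RR; correcting again recovers
        # the generated QTcF to numerical identity
        qtcf = fridericia_qtc(trial.ecg["qt_ms"].to_numpy(),
                              trial.ecg["rr_s"].to_numpy())
        qt_back = qtcf * np.cbrt(trial.ecg["rr_s"].to_numpy())
        np.testing.assert_allclose(qt_back, trial.ecg["qt_ms"], atol=1e-9)

    def test_rr_hr_consistent(self, trial):
        np.testing.assert_allclose(trial.ecg["hr_bpm"],
                                   60.0 / trial.ecg["rr_s"], rtol=1e-9)


class TestNullTruth:
    def test_zero_variance_no_drug_reduces_to_fixed_effects(self):
        truth = QtcTruth(theta_trt=0.0, slope_parent=0.0, d7_slope_parent=0.0,
                         re_sd=(0.0, 0.0, 0.0), sigma=0.0, triplicate_sd=0.0,
                         baseline_period_sd=0.0, baseline_sd=0.0)
        design = TrialDesign(panels=(PanelDesign("A", 1, (540,),
                                                 n_subjects=4, n_active=3),))
        trial = simulate_trial(design, qtc_truth=truth, seed=2)
        qtcf = fridericia_qtc(trial.ecg["qt_ms"].to_numpy(),
                              trial.ecg["rr_s"].to_numpy())
        ecg = trial.ecg.assign(qtcf=qtcf)
        pre = ecg[ecg["nominal_time_h"] == 0]
        np.testing.assert_allclose(pre["qtcf"], truth.baseline_mean, atol=1e-9)
        at2 = ecg[ecg["nominal_time_h"] == 2.0]
        # placebo at 2 h: baseline + intercept + circadian term exactly
        placebo = trial.randomization.loc[
            trial.randomization["treatment"] == "placebo", "subject_id"]
        p2 = at2[at2["subject_id"].isin(set(placebo))]
        np.testing.assert_allclose(
            p2["qtcf"], truth.baseline_mean + truth.theta_int
            + truth.theta_ntime[2.0], atol=1e-9)


class TestTruthRoundTrip:
    def test_large_trial_recovers_fixed_effects_within_2_se(self):
        """Consistency: one 400-subject trial (noise-free triplicates)
        recovers every fixed effect within 2 SE."""
        from cqtc.model import ModelSpec, parameter_table
        from cqtc.simulate import analyze_trial
        panels = tuple(
            PanelDesign(f"A{i}", 1, (180, 540, 900)) for i in range(25)
        ) + tuple(PanelDesign(f"C{i}", 2, (540,), days_dosed=7) for i in range(25))
        design = TrialDesign(panels=panels)
        truth = QtcTruth.model_exact()
        trial = simulate_trial(design, qtc_truth=truth, seed=42)
        fit, slopes, _, _ = analyze_trial(trial)
        table = parameter_table(fit, df_method="residual")
        expected = {
            "intercept": truth.theta_int, "trt": truth.theta_trt,
            "day7": truth.theta_day, "baseline_dev": truth.theta_rmean,
            "cp_parent": truth.slope_parent,
            "day7_cp_parent": truth.d7_slope_parent,
            **{f"ntime_{t:g}": v for t, v in truth.theta_ntime.items()},
        }
        for _, row in table.iterrows():
            z = abs(row["estimate"] - expected[row["term"]]) / row["se"]
            assert z < 2.0, f"{row['term']}: z={z:.2f}"


class TestRecoveryStudy:
    def test_same_seed_identical_and_columns_sane(self):
        # a MAD panel keeps the Day-7 and time-0 class levels populated
        design = TrialDesign(panels=(PanelDesign("C", 2, (540,), days_dosed=7),
                                     PanelDesign("E", 3, (720, 900))))
        kw = dict(design=design, qtc_truth=QtcTruth.model_exact(), seed=4)
        a = recovery_study(2, **kw)
        b = recovery_study(2, **kw)
        pd.testing.assert_frame_equal(a, b)
        assert a["ok"].all()
        assert a["slope_d1_covered"].isin([True, False]).all()

    def test_null_truth_mean_slope_near_zero(self):
        """Truth slope 0: the mean estimate stays within 3 Monte-Carlo SEs
        of zero (scaled-down replicate count for a unit test)."""
        truth = QtcTruth(theta_trt=0.0, slope_parent=0.0, d7_slope_parent=0.0,
                         triplicate_sd=0.0)
        design = TrialDesign(panels=(
            PanelDesign("A", 1, (180, 540, 900)),
            PanelDesign("C", 2, (540,), days_dosed=7)))
        res = recovery_study(30, design=design, qtc_truth=truth, seed=21)
        ok = res[res["ok"]]
        mc_se = ok["slope_d1"].std() / np.sqrt(len(ok))
        assert abs(ok["slope_d1"].mean()) < 3 * mc_se + 1e-9
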