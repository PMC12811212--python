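"""Numeric counterparts of the pre-model exploratory checks and post-fit GOF.

The four exploratory assessments carried out before fitting a C-QTc model
are graphical in routine practice; here each is reduced to a documented
statistic so it can be asserted on (the plots are still available through
the pipeline):

* no drug effect on heart rate - mean change-from-baseline HR by treatment,
  day and nominal time, with the maximum absolute active-vs-placebo contrast;
* adequacy of the Fridericia correction - OLS slope of QTcF on RR with CI
  (adequate when the CI covers 0);
* absence of hysteresis - lag between the time of maximum mean dQTcF and of
  maximum mean concentration on the nominal-time grid, per dose and analyte;
* linearity of the concentration-effect relationship - maximum deviation of
  a LOESS smoother (local-linear, tricube weights) from the straight-line
  fit over the central 90% of the concentration range.

All functions are pure: same input, same output, no hidden state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import DiagnosticsError
from .model import DesignData, FitResult, ModelSpec, build_design


@dataclass
class HeartRateEffect:
    table: pd.DataFrame          # mean dHR by treatment, day, nominal time
    max_abs_contrast: float      # max |active - placebo| over (day, time)
    exclusions: pd.DataFrame     # records without a pre-dose HR baseline


def heart_rate_effect(ecg: pd.DataFrame, assignments: pd.DataFrame) -> HeartRateEffect:
    """Mean change-from-baseline heart rate by treatment, day and time.

    The HR baseline is the Day-1 pre-dose replicate mean of each
    subject-period; records from subject-periods without one are excluded
    and logged.
    """
    df = ecg.copy()
    arm = assignments.set_index(["subject_id", "period"])["treatment"]
    pre = df[(df["day"] == 1) & (df["nominal_time_h"] == 0)]
    base = pre.groupby(["subject_id", "period"])["hr_bpm"].mean()
    keys = pd.MultiIndex.from_frame(df[["subject_id", "period"]])
    has_base = keys.isin(base.index)
    excl = df.loc[~has_base].copy()
    if len(excl):
        excl["reason"] = "no pre-dose HR baseline"
    df = df.loc[has_base].copy()
    df["dhr"] = df["hr_bpm"].to_numpy() - base.reindex(keys[has_base]).to_numpy()
    df["treatment"] = arm.reindex(keys[has_base]).to_numpy()
    table = (df.groupby(["treatment", "day", "nominal_time_h"])["dhr"]
               .mean().rename("mean_dhr_bpm").reset_index())
    wide = table.pivot_table(index=["day", "nominal_time_h"],
                             columns="treatment", values="mean_dhr_bpm")
    if {"active", "placebo"} <= set(wide.columns):
        contrast = float(np.nanmax(np.abs(wide["active"] - wide["placebo"])))
    else:
        contrast = float("nan")
    return HeartRateEffect(table, contrast,
                           excl.reset_index(drop=True) if len(excl) else
                           pd.DataFrame(columns=list(df.columns) + ["reason"]))


@dataclass
class RrAdequacy:
    slope_ms_per_s: float
    ci_low: float
    ci_high: float
    adequate: bool  # two-sided 95% CI covers 0


def rr_adequacy(points: pd.DataFrame, qtcf_col="qtcf_ms", rr_col="rr_s") -> RrAdequacy:
    """OLS slope of QTcF (ms) on RR (s); a flat line means the heart-rate
    correction removed the RR dependence."""
    rr = points[rr_col].astype(float).to_numpy()
    qtcf = points[qtcf_col].astype(float).to_numpy()
    if len(np.unique(rr)) < 3:
        raise DiagnosticsError("need >= 3 distinct RR values")
    if np.std(rr) < 1e-12:
        raise DiagnosticsError("degenerate RR variance; slope undefined")
    res = stats.linregress(rr, qtcf)
    df = len(rr) - 2
    tcrit = stats.t.ppf(0.975, df)
    lo = res.slope - tcrit * res.stderr
    hi = res.slope + tcrit * res.stderr
    return RrAdequacy(float(res.slope), float(lo), float(hi), bool(lo <= 0 <= hi))


@dataclass
class HysteresisLag:
    dose_mg: float
    analyte: str
    t_max_effect_h: float
    t_max_conc_h: float
    lag_h: float
    tie: bool
    loop: pd.DataFrame  # time-ordered (concentration, mean dQTcF) pairs


def _argmax_earliest(times, values):
    values = np.asarray(values, dtype=float)
    mx = np.max(values)
    at = np.flatnonzero(np.isclose(values, mx))
    return float(times[at[0]]), len(at) > 1


def hysteresis_lag(obs: pd.DataFrame, conc_col="cp_parent",
                   analyte="parent") -> list:
    """Per-dose lag between peak mean effect and peak mean concentration.

    ``obs`` is the matched analysis table restricted to active rows, with a
    ``dose_mg`` column.  Ties at the maximum use the earliest grid time and
    are flagged.  Invariant to uniform scaling of the concentrations.
    """
    out = []
    active = obs[obs["trt"] == 1]
    for dose, sub in active.groupby("dose_mg"):
        prof = (sub.groupby("nominal_time_h")
                   .agg(dqtcf=("dqtcf_ms", "mean"), conc=(conc_col, "mean"))
                   .reset_index())
        if len(prof) < 3:
            raise DiagnosticsError(
                f"dose {dose}: need >= 3 nominal times with data")
        t_eff, tie_e = _argmax_earliest(prof["nominal_time_h"].to_numpy(),
                                        prof["dqtcf"].to_numpy())
        t_cmx, tie_c = _argmax_earliest(prof["nominal_time_h"].to_numpy(),
                                        prof["conc"].to_numpy())
        out.append(HysteresisLag(float(dose), analyte, t_eff, t_cmx,
                                 t_eff - t_cmx, tie_e or tie_c,
                                 prof.rename(columns={"conc": "concentration",
                                                      "dqtcf": "mean_dqtcf_ms"})))
    return out


@dataclass
class LinearityCheck:
    analyte: str
    max_abs_deviation_ms: float
    span: float
    n: int


def linearity_check(obs: pd.DataFrame, conc_col="cp_parent", analyte="parent",
                    span=0.75) -> LinearityCheck:
    """Max |LOESS - straight line| over the central 90% concentration range.

    LOESS is the standard local-linear smoother with tricube weights
    (span 0.75 by default).  Requires >= 20 active observations.
    """
    sub = obs[obs["trt"] == 1]
    c = sub[conc_col].astype(float).to_numpy()
    y = sub["dqtcf_ms"].astype(float).to_numpy()
    if len(c) < 20:
        raise DiagnosticsError(f"need >= 20 active observations, got {len(c)}")
    if span * len(c) < 4:
        raise DiagnosticsError("LOESS span too small for the data density")
    coef = np.polyfit(c, y, 1)
    smoothed = lowess(y, c, frac=span, return_sorted=True)
    xs, ys = smoothed[:, 0], smoothed[:, 1]
    lo, hi = np.quantile(c, [0.05, 0.95])
    inside = (xs >= lo) & (xs <= hi)
    dev = np.abs(ys[inside] - np.polyval(coef, xs[inside]))
    return LinearityCheck(analyte, float(np.max(dev)), span, len(c))


@dataclass
class GofSummary:
    resid_mean: float
    resid_skew: float
    by_time: pd.DataFrame        # mean marginal residual per nominal time
    by_treatment: pd.DataFrame   # mean marginal residual per arm
    time_trend_slope: float      # OLS slope of marginal residual on time
    treatment_trend: float       # active-minus-placebo mean residual
    obs_vs_pred_corr: float      # observed vs individual (conditional) prediction


def gof(fit: FitResult, obs: pd.DataFrame, spec: ModelSpec,
        include_day1_predose=False) -> GofSummary:
    """Residual summaries and observed-vs-individual-predicted agreement.

    Marginal residuals are y - X beta; conditional (individual) predictions
    add the empirical-Bayes random effects G Z' V^-1 (y - X beta) per
    subject.
    """
    rows = obs
    if not include_day1_predose and "predose_day1" in obs.columns:
        rows = obs[~obs["predose_day1"].astype(bool)]
    rows = rows.reset_index(drop=True)
    design = build_design(obs, spec, include_day1_predose=include_day1_predose)
    X, Z, y, groups = design.X, design.Z, design.y, design.groups
    q = fit.re_cov.shape[0]
    marg = y - X @ fit.beta
    cond_pred = (X @ fit.beta).copy()
    for g in np.unique(groups):
        m = groups == g
        Zi = Z[m][:, :q]
        if q:
            V = fit.sigma2 * np.eye(m.sum()) + Zi @ fit.re_cov @ Zi.T
            eta = fit.re_cov @ Zi.T @ np.linalg.solve(V, marg[m])
            cond_pred[m] += Zi @ eta
    df = pd.DataFrame({
        "nominal_time_h": rows["nominal_time_h"].astype(float),
        "trt": X[:, design.fe_names.index("trt")],
        "marg": marg,
    })
    by_time = df.groupby("nominal_time_h")["marg"].agg(["mean", "count"]).reset_index()
    by_trt = df.groupby("trt")["marg"].agg(["mean", "count"]).reset_index()
    trend = stats.linregress(df["nominal_time_h"].astype(float), marg).slope
    trt_means = by_trt.set_index("trt")["mean"]
    trt_diff = float(trt_means.get(1, np.nan) - trt_means.get(0, np.nan))
    corr = float(np.corrcoef(y, cond_pred)[0, 1]) if np.std(cond_pred) > 0 else np.nan
    return GofSummary(float(marg.mean()), float(stats.skew(marg)),
                      by_time, by_trt, float(trend), trt_diff, corr)
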