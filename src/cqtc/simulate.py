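"""Synthetic phase-1 SAD/MAD trial generator with known truth.

Emulates the three-part single-centre dose-escalation design used for the
C-QTc analysis: Part 1, two crossover single-ascending-dose panels of 8
female subjects (6:2 active:placebo per period; doses 180/540/900 and
360/720/900 mg); Part 2, two multiple-ascending-dose panels (540 and 720 mg
QD for 7 days, full ECG/PK days 1 and 7 plus 2-h ECGs on days 3/5); Part 3,
one single-dose male panel (720 and 900 mg over two periods).  Triplicate
ECGs at nominal 0/1/2/4/8/24 h; PK at 0/1/1.5/2/3/4/6/8/12/16/24/48 h;
metabolite concentrations measured in Parts 1-2 only.

Pharmacokinetics are linear: an absorption-convolved biexponential for the
parent (dose-proportional by construction, biphasic decline, configurable
terminal half-life, default 9.6 h effective) and first-order
formation/elimination for the metabolite; multiple dosing by superposition.
The QTc truth is the same linear mixed model the pipeline fits, applied on
top of a subject/period resting baseline, so that parameter-recovery and
coverage studies are meaningful.  All randomness flows from a single seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import assemble, ecg as ecg_mod
from .errors import ConfigurationError
from .model import ModelSpec, fit_with_ladder, slope_summaries
from .predict import PredictionScenario, predict

ECG_TIMES_H = (0.0, 1.0, 2.0, 4.0, 8.0, 24.0)
PK_TIMES_H = (0.0, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 16.0, 24.0, 48.0)


# ---------------------------------------------------------------------------
# trial design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PanelDesign:
    name: str
    part: int
    periods: tuple            # dose (mg) administered in each period
    n_subjects: int = 8
    n_active: int = 6
    days_dosed: int = 1       # 7 for the MAD panels
    sex: str = "female"


@dataclass(frozen=True)
class TrialDesign:
    panels: tuple
    ecg_times_h: tuple = ECG_TIMES_H
    pk_times_h: tuple = PK_TIMES_H
    replicate_count: int = 3
    washout_days: int = 6
    metabolite_parts: tuple = (1, 2)   # parts with measured metabolite PK

    @staticmethod
    def default() -> "TrialDesign":
        return TrialDesign(panels=(
            PanelDesign("A", 1, (180, 540, 900)),
            PanelDesign("B", 1, (360, 720, 900)),
            PanelDesign("C", 2, (540,), days_dosed=7),
            PanelDesign("D", 2, (720,), days_dosed=7),
            PanelDesign("E", 3, (720, 900), sex="male"),
        ))

    def ecg_schedule(self, panel: PanelDesign):
        """(period, day, times) sessions for one panel."""
        out = []
        for per in range(1, len(panel.periods) + 1):
            if panel.days_dosed >= 7:
                out += [(per, 1, self.ecg_times_h), (per, 3, (2.0,)),
                        (per, 5, (2.0,)), (per, 7, self.ecg_times_h)]
            else:
                out.append((per, 1, self.ecg_times_h))
        return out

    def pk_schedule(self, panel: PanelDesign):
        out = []
        for per in range(1, len(panel.periods) + 1):
            if panel.days_dosed >= 7:
                out += [(per, 1, self.pk_times_h), (per, 5, (0.0,)),
                        (per, 7, self.pk_times_h)]
            else:
                out.append((per, 1, self.pk_times_h))
        return out

    def expected_ecg_rows(self) -> int:
        total = 0
        for panel in self.panels:
            pts = sum(len(times) for _, _, times in self.ecg_schedule(panel))
            total += panel.n_subjects * pts * self.replicate_count
        return total


# ---------------------------------------------------------------------------
# truth parameter sets
# ---------------------------------------------------------------------------

@dataclass
class PkTruth:
    """Linear-PK truth: absorption-convolved biexponential parent,
    first-order metabolite.

    ``scale_per_mg`` converts the unit-dose shape to µg/mL per mg of dose;
    defaults are calibrated so the 45-mg QD steady-state Cmax of each analyte
    is near the 0.375 µg/mL therapeutic concentration, tmax falls in the
    1.5-4 h window, and the terminal phase follows the configured 9.6-h
    effective half-life.
    """

    ka_per_h: float = 0.7
    lambda1_per_h: float = 0.30
    half_life_h: float = 9.6
    frac_fast: float = 0.75
    scale_per_mg: float = None
    metab_lambda_per_h: float = 0.12
    metab_scale: float = None
    lloq_ug_ml: float = 0.005
    iiv_cv: dict = field(default_factory=lambda: {
        "scale": 0.30, "ka": 0.30, "lambda2": 0.10, "metab_scale": 0.25})

    @property
    def lambda2_per_h(self) -> float:
        return math.log(2.0) / self.half_life_h

    def __post_init__(self):
        for lam in (self.lambda1_per_h, self.lambda2_per_h):
            if abs(self.metab_lambda_per_h - lam) < 1e-9 or \
               abs(self.metab_lambda_per_h - self.ka_per_h) < 1e-9:
                raise ConfigurationError(
                    "metabolite rate must differ from parent rates")
        if self.scale_per_mg is None or self.metab_scale is None:
            self._calibrate()

    def _calibrate(self, target_cmax=0.375, dose_mg=45.0, n_doses=7):
        """Choose the scales so 45-mg QD steady-state Cmax = 0.375 µg/mL."""
        grid = np.linspace(0.0, 24.0, 2401) + (n_doses - 1) * 24.0
        unit = _superpose(grid, 1.0, n_doses, self.ka_per_h, self.lambda1_per_h,
                          self.lambda2_per_h, self.frac_fast, 1.0)
        self.scale_per_mg = float(target_cmax / (dose_mg * unit.max()))
        munit = _superpose(grid, 1.0, n_doses, self.ka_per_h, self.lambda1_per_h,
                           self.lambda2_per_h, self.frac_fast, 1.0,
                           metab_lambda=self.metab_lambda_per_h, metab_scale=1.0)
        self.metab_scale = float(target_cmax / (dose_mg * self.scale_per_mg *
                                                munit.max()))


@dataclass
class QtcTruth:
    """Generative parameters of the dQTcF mixed model plus the measurement
    layer (resting baseline, triplicate scatter, heart-rate model).

    The concentration slopes default to published-scale values; the variance
    components, baseline distribution and circadian (nominal-time) effects
    are plausible placeholders - no published source pins them - and are
    flagged as such in the emitted truth file.
    """

    theta_int: float = 0.8
    theta_trt: float = 2.27
    theta_day: float = -0.5
    theta_rmean: float = -0.3
    theta_ntime: dict = field(default_factory=lambda: {
        1.0: 1.5, 2.0: 4.0, 4.0: 5.0, 8.0: 3.5, 24.0: 0.5})
    slope_parent: float = -0.5071
    d7_slope_parent: float = 0.1449          # Day-7 slope -0.3622
    slope_metabolite: float = 0.0
    d7_slope_metabolite: float = 0.0
    re_sd: tuple = (4.0, 1.5, 0.0)           # intercept, parent slope, metab slope
    re_corr_int_slope: float = -0.2
    sigma: float = 5.0                       # timepoint residual SD (ms)
    triplicate_sd: float = 4.0               # within-triplicate SD (ms)
    baseline_mean: float = 410.0
    baseline_sd: float = 12.0
    baseline_period_sd: float = 4.0
    hr_mean: float = 63.0
    hr_sd: float = 7.0
    hr_time_sd: float = 3.0
    hr_rep_sd: float = 1.5
    hr_drug_effect_per_ugml: float = 0.0     # no HR drug effect by default

    @staticmethod
    def model_exact() -> "QtcTruth":
        """Truth under which the assembled dQTcF data follow the analysis
        model exactly.

        With replicate-level scatter present, the measured baseline carries
        noise that the baseline subtraction propagates into every row of a
        period as a shared error term outside the fitted model; zeroing the
        within-triplicate SD removes it, so recovery and coverage studies
        probe the estimator rather than that (separately documented)
        baseline-measurement effect.
        """
        return QtcTruth(triplicate_sd=0.0)

    @staticmethod
    def parent_metabolite_default() -> "QtcTruth":
        """Truth with both analyte effects at published-scale slopes."""
        return QtcTruth(theta_trt=1.1068,
                        slope_parent=-1.5319, d7_slope_parent=0.8064,
                        slope_metabolite=2.4566, d7_slope_metabolite=-1.6826,
                        re_sd=(4.0, 1.5, 1.5))

    @property
    def G(self) -> np.ndarray:
        sd = np.asarray(self.re_sd, dtype=float)
        G = np.diag(sd ** 2)
        G[0, 1] = G[1, 0] = self.re_corr_int_slope * sd[0] * sd[1]
        return G

    def ddqtcf(self, cp_parent, cp_metabolite=0.0, day=1) -> float:
        """True placebo-corrected effect at a concentration pair."""
        d7 = 1.0 if day == 7 else 0.0
        return (self.theta_trt
                + (self.slope_parent + d7 * self.d7_slope_parent) * cp_parent
                + (self.slope_metabolite + d7 * self.d7_slope_metabolite)
                * cp_metabolite)


# ---------------------------------------------------------------------------
# pharmacokinetic curves (sums of exponentials, superposition)
# ---------------------------------------------------------------------------

def _biexp_abs(t, ka, lam):
    """Unit absorption-elimination term ka/(ka-lam)(e^-lam t - e^-ka t),
    with the l'Hopital limit ka*t*e^(-ka t) when the rates collide.

    ``ka`` may vary per element (inter-individual variability)."""
    t = np.asarray(t, dtype=float)
    ka = np.broadcast_to(np.asarray(ka, dtype=float), t.shape).copy()
    out = np.zeros_like(t)
    pos = t > 0
    collide = np.abs(ka - lam) < 1e-8 * np.maximum(ka, lam)
    m = pos & collide
    out[m] = ka[m] * t[m] * np.exp(-ka[m] * t[m])
    m = pos & ~collide
    out[m] = ka[m] / (ka[m] - lam) * (np.exp(-lam * t[m]) - np.exp(-ka[m] * t[m]))
    return out


def _single_dose_unit(t, ka, lam1, lam2, frac):
    """Noise-free unit-dose parent shape (per mg before scaling)."""
    return frac * _biexp_abs(t, ka, lam1) + (1 - frac) * _biexp_abs(t, ka, lam2)


def _metab_term(t, ka, lam, lam_m):
    """Convolution of a parent component with first-order metabolite
    elimination: integral of _biexp_abs against e^(-lam_m (t-s))."""
    t = np.asarray(t, dtype=float)
    ka = np.broadcast_to(np.asarray(ka, dtype=float), t.shape).copy()
    out = np.zeros_like(t)
    pos = t > 0
    collide = np.abs(ka - lam) < 1e-8 * np.maximum(ka, lam)
    m = pos & collide
    if m.any():
        # limit form ka * s * e^{-ka s} convolved with e^{-lam_m (t-s)}
        d = ka[m] - lam_m
        out[m] = ka[m] * (np.exp(-lam_m * t[m])
                          - np.exp(-ka[m] * t[m]) * (1 + d * t[m])) / d ** 2
    m = pos & ~collide
    if m.any():
        c = ka[m] / (ka[m] - lam)
        out[m] = c * ((np.exp(-lam * t[m]) - np.exp(-lam_m * t[m])) / (lam_m - lam)
                      - (np.exp(-ka[m] * t[m]) - np.exp(-lam_m * t[m]))
                      / (lam_m - ka[m]))
    return out


def _single_dose_metab_unit(t, ka, lam1, lam2, frac, lam_m):
    return (frac * _metab_term(t, ka, lam1, lam_m)
            + (1 - frac) * _metab_term(t, ka, lam2, lam_m))


def _superpose(t_global, dose_mg, n_doses, ka, lam1, lam2, frac, scale,
               metab_lambda=None, metab_scale=None):
    """Sum single-dose curves for QD doses at 0, 24, ... (n_doses-1)*24 h.

    Vectorised over rows; ``n_doses`` may be an array (doses given up to the
    measurement day).  Exactly linear in dose (dose-proportionality
    contract).
    """
    t_global = np.asarray(t_global, dtype=float)
    dose = np.broadcast_to(np.asarray(dose_mg, dtype=float), t_global.shape)
    nd = np.broadcast_to(np.asarray(n_doses), t_global.shape)
    ka = np.broadcast_to(np.asarray(ka, dtype=float), t_global.shape)
    total = np.zeros_like(t_global)
    for k in range(int(np.max(nd))):
        mask = nd > k
        if not mask.any():
            break
        tt = t_global[mask] - 24.0 * k
        if np.isscalar(ka) or ka.shape == ():
            kam = ka
        else:
            kam = ka[mask]
        if metab_lambda is None:
            total[mask] += _single_dose_unit(tt, kam, lam1, lam2, frac)
        else:
            total[mask] += _single_dose_metab_unit(tt, kam, lam1, lam2, frac,
                                                   metab_lambda)
    out = dose * scale * total
    if metab_lambda is not None and metab_scale is not None:
        out = out * metab_scale
    return out


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _subject_table(design: TrialDesign) -> pd.DataFrame:
    rows = []
    for panel in design.panels:
        for i in range(panel.n_subjects):
            rows.append({"subject_id": f"P{panel.part}{panel.name}-{i + 1:02d}",
                         "part": panel.part, "panel": panel.name,
                         "sex": panel.sex})
    return pd.DataFrame(rows)


def randomize(design: TrialDesign, rng) -> pd.DataFrame:
    """6:2 active:placebo assignment, re-randomised each period for the
    crossover SAD/single-dose panels and once for the MAD panels."""
    rows = []
    for panel in design.panels:
        ids = [f"P{panel.part}{panel.name}-{i + 1:02d}"
               for i in range(panel.n_subjects)]
        mad_placebo = None
        if panel.days_dosed >= 7:
            mad_placebo = set(rng.permutation(ids)[: panel.n_subjects - panel.n_active])
        for per, dose in enumerate(panel.periods, start=1):
            if mad_placebo is not None:
                placebo = mad_placebo
            else:
                placebo = set(rng.permutation(ids)[: panel.n_subjects - panel.n_active])
            for sid in ids:
                trt = "placebo" if sid in placebo else "active"
                rows.append({"subject_id": sid, "part": panel.part,
                             "panel": panel.name, "period": per,
                             "treatment": trt,
                             "dose_mg": dose if trt == "active" else 0})
    return pd.DataFrame(rows)


def _draw_pk_params(subjects: pd.DataFrame, truth: PkTruth, rng,
                    noise_free=False) -> pd.DataFrame:
    def mult(cv, n):
        if noise_free or cv <= 0:
            return np.ones(n)
        s = math.sqrt(math.log(1 + cv ** 2))
        return np.exp(rng.normal(-0.5 * s * s, s, n))

    n = len(subjects)
    return pd.DataFrame({
        "subject_id": subjects["subject_id"],
        "scale": truth.scale_per_mg * mult(truth.iiv_cv.get("scale", 0), n),
        "ka": truth.ka_per_h * mult(truth.iiv_cv.get("ka", 0), n),
        "lambda2": truth.lambda2_per_h * mult(truth.iiv_cv.get("lambda2", 0), n),
        "metab_scale": truth.metab_scale * mult(truth.iiv_cv.get("metab_scale", 0), n),
    })


def _conc_at(points: pd.DataFrame, params: pd.DataFrame, truth: PkTruth,
             analyte: str) -> np.ndarray:
    """Model concentration for each (subject, period, day, time) row.

    ``points`` needs subject_id, day, nominal_time_h and dose_mg (0 for
    placebo rows, which therefore come out exactly 0).
    """
    p = points.merge(params, on="subject_id", how="left", validate="m:1")
    t_global = (p["day"].to_numpy(dtype=float) - 1.0) * 24.0 \
        + p["nominal_time_h"].to_numpy(dtype=float)
    n_doses = p["day"].to_numpy(dtype=int)  # QD dosing up to the sampling day
    kwargs = {}
    if analyte == "metabolite":
        kwargs = {"metab_lambda": truth.metab_lambda_per_h,
                  "metab_scale": p["metab_scale"].to_numpy()}
    lam2 = p["lambda2"].to_numpy()
    # lambda2 varies per subject: evaluate per unique value to keep the
    # exponential helpers scalar in the rates
    out = np.zeros(len(p))
    for lam in np.unique(lam2):
        m = lam2 == lam
        out[m] = _superpose(t_global[m], p.loc[m, "dose_mg"].to_numpy(dtype=float),
                            n_doses[m], p.loc[m, "ka"].to_numpy(),
                            truth.lambda1_per_h, lam, truth.frac_fast,
                            p.loc[m, "scale"].to_numpy(),
                            **({k: (v[m] if isinstance(v, np.ndarray) else v)
                                for k, v in kwargs.items()}))
    return out


def simulate_pk(design: TrialDesign, truth: PkTruth, seed=0, *,
                assignments: pd.DataFrame = None, params: pd.DataFrame = None,
                noise_free=False) -> pd.DataFrame:
    """Scheduled PK samples for the whole trial (long format, µg/mL).

    Values below the LLOQ (and all placebo samples) are reported as 0 with
    ``blq`` set - the assay reports no quantifiable number there.
    """
    rng = np.random.default_rng(seed)
    subjects = _subject_table(design)
    if assignments is None:
        assignments = randomize(design, rng)
    if params is None:
        params = _draw_pk_params(subjects, truth, rng, noise_free=noise_free)

    rows = []
    for panel in design.panels:
        ids = subjects.loc[subjects["panel"].eq(panel.name)
                           & subjects["part"].eq(panel.part), "subject_id"]
        for per, day, times in design.pk_schedule(panel):
            for sid in ids:
                for t in times:
                    rows.append((sid, panel.part, panel.name, per, day, t))
    pk = pd.DataFrame(rows, columns=["subject_id", "part", "panel", "period",
                                     "day", "nominal_time_h"])
    pk = pk.merge(assignments[["subject_id", "period", "dose_mg"]],
                  on=["subject_id", "period"], how="left", validate="m:1")

    frames = []
    for analyte in ("parent", "metabolite"):
        sub = pk if analyte == "parent" else pk[pk["part"].isin(design.metabolite_parts)]
        sub = sub.copy()
        conc = _conc_at(sub, params, truth, analyte)
        blq = conc < truth.lloq_ug_ml
        sub["analyte"] = analyte
        sub["concentration"] = np.where(blq, 0.0, conc)
        sub["blq"] = blq
        frames.append(sub)
    out = pd.concat(frames, ignore_index=True)
    out["unit"] = "µg/mL"
    return out.drop(columns=["dose_mg"]).sort_values(
        ["part", "panel", "subject_id", "period", "day", "nominal_time_h",
         "analyte"]).reset_index(drop=True)


def simulate_ecg(design: TrialDesign, pk_at_ecg: pd.DataFrame, truth: QtcTruth,
                 seed=0) -> pd.DataFrame:
    """Replicate-level ECG records generated from the mixed-model truth.

    ``pk_at_ecg`` must carry cp_parent/cp_metabolite for every scheduled ECG
    point (the trial driver builds it from the PK model, including the
    Part-2 Day-3/5 ECG times that have no PK draw).  The Day-1 pre-dose
    triplicate is the subject-period resting baseline plus replicate
    scatter; every later timepoint adds the model's fixed effects, the
    subject's random effects times [1, cp] and a shared timepoint residual.
    QT is back-computed from QTcF and a drug-free heart-rate model so the
    stored record carries raw QT/RR (Fridericia round-trips exactly).
    """
    rng = np.random.default_rng(seed)
    pts = pk_at_ecg.copy()
    need = {"subject_id", "part", "panel", "period", "day", "nominal_time_h",
            "trt", "cp_parent", "cp_metabolite"}
    if not need <= set(pts.columns):
        raise ConfigurationError(f"pk_at_ecg missing columns {sorted(need - set(pts.columns))}")
    pts = pts.sort_values(["part", "panel", "subject_id", "period", "day",
                           "nominal_time_h"]).reset_index(drop=True)

    subjects = pts["subject_id"].drop_duplicates().tolist()
    sidx = {s: i for i, s in enumerate(subjects)}
    n_sub = len(subjects)
    b_subj = truth.baseline_mean + rng.normal(0, truth.baseline_sd, n_sub)
    # svd method tolerates the PSD-but-singular G of zeroed variance components
    eta = rng.multivariate_normal(np.zeros(3), truth.G, size=n_sub, method="svd")
    hr_subj = truth.hr_mean + rng.normal(0, truth.hr_sd, n_sub)

    sp = pts[["subject_id", "period"]].drop_duplicates().reset_index(drop=True)
    spidx = {(s, p): i for i, (s, p) in enumerate(sp.itertuples(index=False))}
    b_period = (b_subj[[sidx[s] for s in sp["subject_id"]]]
                + rng.normal(0, truth.baseline_period_sd, len(sp)))

    # measured baseline per subject-period: pre-dose triplicate, averaged and
    # rounded exactly as the pipeline will do it
    pre_delta = rng.normal(0, truth.triplicate_sd,
                           (len(sp), design.replicate_count))
    pre_reps = b_period[:, None] + pre_delta
    b_hat = ecg_mod.round_half_away(pre_reps.mean(axis=1))
    indiv = pd.Series(b_hat).groupby(sp["subject_id"].to_numpy()).mean()
    b_gm = float(indiv.mean())

    si = np.array([sidx[s] for s in pts["subject_id"]])
    spi = np.array([spidx[(s, p)]
                    for s, p in pts[["subject_id", "period"]].itertuples(index=False)])
    day = pts["day"].to_numpy(dtype=float)
    t = pts["nominal_time_h"].to_numpy(dtype=float)
    trt = pts["trt"].to_numpy(dtype=float)
    d7 = (day == 7).astype(float)
    cp_p = pts["cp_parent"].to_numpy(dtype=float)
    cp_m = np.nan_to_num(pts["cp_metabolite"].to_numpy(dtype=float))
    predose1 = (day == 1) & (t == 0)

    ntime_eff = np.array([truth.theta_ntime.get(x, 0.0) for x in t])
    eff = (truth.theta_int + truth.theta_trt * trt + truth.theta_day * d7
           + truth.theta_rmean * (b_hat[spi] - b_gm) + ntime_eff
           + (truth.slope_parent + truth.d7_slope_parent * d7 + eta[si, 1]) * cp_p
           + (truth.slope_metabolite + truth.d7_slope_metabolite * d7
              + eta[si, 2]) * cp_m
           + eta[si, 0])
    eps = rng.normal(0, truth.sigma, len(pts))
    mean_qtcf = np.where(predose1, b_period[spi], b_period[spi] + eff + eps)

    R = design.replicate_count
    delta = rng.normal(0, truth.triplicate_sd, (len(pts), R))
    delta[predose1] = pre_delta[spi[predose1]]
    qtcf_reps = mean_qtcf[:, None] + delta

    hr_t = (hr_subj[si] + rng.normal(0, truth.hr_time_sd, len(pts))
            + truth.hr_drug_effect_per_ugml * cp_p)
    hr_reps = np.clip(hr_t[:, None] + rng.normal(0, truth.hr_rep_sd, (len(pts), R)),
                      40.0, 130.0)
    rr_reps = 60.0 / hr_reps
    qt_reps = qtcf_reps * np.cbrt(rr_reps)

    base = pts[["subject_id", "part", "panel", "period", "day",
                "nominal_time_h"]]
    out = base.loc[base.index.repeat(R)].reset_index(drop=True)
    out["replicate"] = np.tile(np.arange(1, R + 1), len(pts))
    out["qt_ms"] = qt_reps.ravel()
    out["rr_s"] = rr_reps.ravel()
    out["hr_bpm"] = 60.0 / out["rr_s"]
    return out


@dataclass
class SimulatedTrial:
    ecg: pd.DataFrame
    pk: pd.DataFrame
    randomization: pd.DataFrame
    truth: dict

    def write(self, outdir):
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.ecg.to_csv(outdir / "ecg.csv", index=False)
        self.pk.to_csv(outdir / "pk.csv", index=False)
        self.randomization.to_csv(outdir / "randomization.csv", index=False)
        (outdir / "truth.json").write_text(json.dumps(self.truth, indent=2,
                                                      default=float))
        return outdir


def simulate_trial(design: TrialDesign = None, pk_truth: PkTruth = None,
                   qtc_truth: QtcTruth = None, seed=0,
                   noise_free=False) -> SimulatedTrial:
    """Full trial: randomization, PK draws, triplicate ECGs, truth record.

    Deterministic given the seed (same seed, byte-identical outputs).
    ``noise_free`` switches off inter-individual PK variability (the QTc
    variance components can be zeroed through ``qtc_truth``).
    """
    design = design or TrialDesign.default()
    pk_truth = pk_truth or PkTruth()
    qtc_truth = qtc_truth or QtcTruth()
    root = np.random.SeedSequence(seed)
    s_rand, s_pk, s_ecg = [np.random.default_rng(c) for c in root.spawn(3)]

    subjects = _subject_table(design)
    assignments = randomize(design, s_rand)
    params = _draw_pk_params(subjects, pk_truth, s_pk, noise_free=noise_free)
    pk = simulate_pk(design, pk_truth, assignments=assignments, params=params,
                     seed=0, noise_free=noise_free)

    # concentrations at every scheduled ECG point (Part-2 Day-3/5 ECG times
    # have no PK draw; the generator inserts the model value explicitly)
    rows = []
    for panel in design.panels:
        ids = subjects.loc[subjects["panel"].eq(panel.name)
                           & subjects["part"].eq(panel.part), "subject_id"]
        for per, day, times in design.ecg_schedule(panel):
            for sid in ids:
                for tt in times:
                    rows.append((sid, panel.part, panel.name, per, day, tt))
    pts = pd.DataFrame(rows, columns=["subject_id", "part", "panel", "period",
                                      "day", "nominal_time_h"])
    pts = pts.merge(assignments[["subject_id", "period", "treatment", "dose_mg"]],
                    on=["subject_id", "period"], how="left", validate="m:1")
    pts["trt"] = (pts["treatment"] == "active").astype(int)
    for analyte, col in (("parent", "cp_parent"), ("metabolite", "cp_metabolite")):
        conc = _conc_at(pts, params, pk_truth, analyte)
        pts[col] = np.where(conc < pk_truth.lloq_ug_ml, 0.0, conc)
    ecg = simulate_ecg(design, pts, qtc_truth, seed=s_ecg.integers(2 ** 31))

    truth = {
        "seed": seed,
        "pk": {k: v for k, v in asdict(pk_truth).items()},
        "qtc": {k: v for k, v in asdict(qtc_truth).items()},
        "provenance": {
            "slopes": "published-scale defaults",
            "variance_components": "placeholders (not published)",
            "baseline_and_hr": "placeholders (not published)",
        },
    }
    truth["qtc"]["theta_ntime"] = {str(k): v for k, v in qtc_truth.theta_ntime.items()}
    rand_cols = ["subject_id", "part", "panel", "period", "treatment", "dose_mg"]
    return SimulatedTrial(ecg, pk, assignments[rand_cols], truth)


# ---------------------------------------------------------------------------
# end-to-end recovery / coverage harness
# ---------------------------------------------------------------------------

def analyze_trial(trial: SimulatedTrial, spec: ModelSpec = None,
                  scenario: PredictionScenario = None, seed=0):
    """simulate -> preprocess -> assemble -> fit -> (predict) for one trial.

    Returns (fit, slopes, prediction, matched) - the pieces the recovery
    study aggregates.
    """
    spec = spec or ModelSpec("parent")
    points = ecg_mod.qtcf_points(trial.ecg)
    baselines = ecg_mod.compute_baselines(points)
    dq = ecg_mod.compute_dqtcf(points, baselines)
    matched, _ = assemble.assemble_dataset(dq, trial.pk, trial.randomization,
                                           baselines, input_unit="µg/mL")
    if spec.kind == "parent_metabolite":
        parts12 = trial.randomization.loc[trial.randomization["part"].isin((1, 2)),
                                          "subject_id"].unique()
        matched = matched[matched["subject_id"].isin(parts12)]
    fit = fit_with_ladder(matched, spec, seed=seed)
    slopes = slope_summaries(fit, spec)
    pred = predict(fit, scenario, spec) if scenario is not None else None
    return fit, slopes, pred, matched


def recovery_study(n_replicates, design=None, pk_truth=None, qtc_truth=None,
                   seed=0, scenario=None, spec=None) -> pd.DataFrame:
    """Monte-Carlo parameter-recovery/coverage study over full pipeline runs.

    One row per replicate: Day-1 slope estimate with CI, whether the CI
    covers the truth, the structure the ladder settled on and, when a
    scenario is given, the ddQTcF upper one-sided 95% bound and whether it
    exceeds the true scenario effect.  Individual replicate failures are
    recorded, not fatal.
    """
    if n_replicates < 2:
        raise ConfigurationError("need at least 2 replicates")
    design = design or TrialDesign.default()
    pk_truth = pk_truth or PkTruth()
    qtc_truth = qtc_truth or QtcTruth()
    spec = spec or ModelSpec("parent")
    seeds = np.random.SeedSequence(seed).spawn(n_replicates)
    rows = []
    for rep, ss in enumerate(seeds):
        rep_seed = int(ss.generate_state(1)[0] % (2 ** 31))
        trial = simulate_trial(design, pk_truth, qtc_truth, seed=rep_seed)
        row = {"replicate": rep, "seed": rep_seed, "ok": True, "error": ""}
        try:
            fit, slopes, pred, _ = analyze_trial(trial, spec, scenario,
                                                 seed=rep_seed)
            s1 = next(s for s in slopes if s.day == 1 and s.analyte == "parent")
            row.update(structure=fit.structure_used, loglik=fit.loglik,
                       slope_d1=s1.estimate, slope_d1_se=s1.se,
                       slope_d1_lo=s1.ci_low, slope_d1_hi=s1.ci_high,
                       slope_d1_covered=bool(s1.ci_low <= qtc_truth.slope_parent
                                             <= s1.ci_high))
            if pred is not None:
                true_dd = qtc_truth.ddqtcf(pred.scenario.cp_parent,
                                           pred.scenario.cp_metabolite,
                                           pred.scenario.day)
                row.update(ddqtcf=pred.ddqtcf_ms,
                           upper95=pred.upper_95_one_sided_ms,
                           true_ddqtcf=true_dd,
                           upper_exceeds_truth=bool(
                               pred.upper_95_one_sided_ms > true_dd))
        except Exception as exc:  # replicate failure: count, don't die
            row.update(ok=False, error=f"{type(exc).__name__}: {exc}")
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_recovery(results: pd.DataFrame, truth: QtcTruth) -> dict:
    ok = results[results["ok"]]
    out = {"n_replicates": len(results), "n_ok": int(len(ok)),
           "n_failed": int((~results["ok"]).sum())}
    if len(ok):
        est = ok["slope_d1"].to_numpy()
        out.update(
            slope_truth=truth.slope_parent,
            slope_mean=float(est.mean()),
            slope_bias=float(est.mean() - truth.slope_parent),
            slope_rmse=float(np.sqrt(np.mean((est - truth.slope_parent) ** 2))),
            slope_ci_coverage=float(ok["slope_d1_covered"].mean()),
        )
        if "upper_exceeds_truth" in ok:
            out["upper_one_sided_coverage"] = float(ok["upper_exceeds_truth"].mean())
    return out
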