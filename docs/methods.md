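# Methods

## The analysis model

Both C–QTc models regress dQTcF (ms) on plasma concentration (µg/mL) with
class effects for treatment (placebo/active), day (Day 1/Day 7) and nominal
time (0, 1, 2, 4, 8, 24 h; 0 h is the reference level), a continuous
regression-to-the-mean term (deviation of the subject-period baseline from
the grand mean baseline), day-specific concentration slopes via a Day-7 ×
slope interaction, and per-subject random effects on intercept and each
concentration slope. The parent-only model has 11 fixed-effect columns and
a 2×2 random-effects covariance G; the parent+metabolite model has 13 and a
3×3 G. Baselines are hierarchical: the period baseline is the rounded
Day-1 pre-dose triplicate average; the individual baseline averages a
subject's period baselines; the grand mean averages individual baselines so
each subject counts once however many periods they entered.

**Day-1 pre-dose rows.** Because the analysis value at Day-1/0 h *is* the
baseline, its dQTcF is identically zero for every subject in both arms — a
structural zero that cannot carry a treatment effect. The assembled
dataset retains these rows (flagged `predose_day1`) for audit and for the
accounting invariants, but model fitting excludes them by default: fitting
a nonzero θ_TRT model to rows that are zero by construction biases both the
treatment effect and, through the concentration lever, the slope. The
nominal-time-0 reference level remains populated by the Day-7 pre-dose
(trough) rows of the multiple-dose part, so the design stays full rank.
`fit_model`-level callers can re-include the rows with
`include_day1_predose=True`.

**Estimation.** Maximum likelihood, not REML (`sigma2` equals RSS/n in the
no-random-effects limit, which the tests verify against the (n−p)/n closed
form). For each variance-parameter iterate the fixed effects are profiled
out by generalized least squares on per-subject blocks (V_i = Z_i G Z_iᵀ +
σ²I); the variance parameters — G through a log-Cholesky factor, σ through
log σ — are optimized with bounded L-BFGS-B, three seeded restarts before a
fit is declared non-converged. Convergence requires optimizer success, a
projected gradient of the *mean* (per-observation) log-likelihood below
1e-6 in every coordinate (the gradient of the summed likelihood of ~500
observations is below finite-difference noise at that tolerance), and a
positive-definite fixed-effects covariance. A perfect linear fit is
detected up front and returned in closed form with σ² at its floor.
Numerical floors: σ² ≥ 1e-10; G is positive semidefinite by construction of
the Cholesky parameterization; log-SD parameters are bounded in
[log 1e-5, log 1e4].

**Simplification ladder.** The unstructured random-effects covariance is
attempted first; on non-convergence the fit demotes to diagonal, then
intercept-only, recording every attempt. This mirrors the pre-specified
practice of simplifying an over-parameterized model only when it fails to
converge.

**Degrees of freedom.** Contrast df use the Satterthwaite approximation:
df = 2v²/Var(v) with v = Lᵀ C(θ) L, the gradient of v and the
variance-parameter covariance (inverse observed information of the profiled
likelihood) both taken in the internal log-Cholesky coordinates, so the
parameterization cancels. Residual df (n − p) is the documented fallback
when the information matrix is degenerate, and is available as an explicit
option. Kenward–Roger df are not implemented; at this design size (40
subjects, ~500 observations) the df choice moves one-sided bounds by well
under 0.1 ms, and the point predictions are df-free.

## Predictions

ddQTcF is the model-based active-minus-placebo difference at equal
covariates, so every term not interacted with treatment or concentration —
intercept, Day-7 shift, baseline deviation, nominal-time class — cancels.
The contrast therefore weights θ_TRT by 1, each analyte slope by its
scenario concentration, and each Day-7 interaction by the same
concentration when the scenario is Day 7. This reading is validated by the
internal-consistency identities among the published prediction cells (the
Day-1 and Day-7 implied treatment-effect terms agree to 1e-4, and all
higher-exposure cells follow from the therapeutic-concentration anchor to
printed precision). The upper one-sided 95% bound is point +
t(0.95, df)·SE.

Scenario construction scales a reference Cmax by dose under linear PK
(0.244 µg/mL at 30 mg → 0.366 at 45 mg) with the therapeutic concentration
itself an explicit configuration value (default override 0.375 µg/mL,
since the published rounding rule for "approximately 0.375" is not
stated), fold multipliers {1, 6, 10}, and scenario metabolite
concentrations equal to the parent ones by default. Predictions are
reported to 4 decimals.

## Diagnostics

Each of the four pre-model graphical checks is reduced to a documented
statistic (the plots remain available): mean change-from-baseline heart
rate by arm/day/time with the maximum active-vs-placebo contrast; the OLS
slope of QTcF on RR with a 95% CI and an "adequate when the CI covers 0"
flag; the lag between the nominal-time grid maxima of mean dQTcF and mean
concentration per dose (ties resolve to the earliest time and are
flagged); and the maximum deviation between a LOESS smoother
(local-linear, tricube weights, span 0.75) and the straight-line fit over
the central 90% of the concentration range. Post-fit summaries cover
marginal and conditional (empirical-Bayes) residuals, per-time and per-arm
residual means with trend slopes, and the observed vs individual-predicted
correlation. All flags are advisory statistics, never gates that halt the
pipeline. Caveat: the RR-adequacy CI treats points as independent; with
strong between-subject clustering (shared subject HR and baseline) it is
optimistic, which is why the bundle reports the pre-dose-only variant
alongside the all-data one.

## The trial simulator

The default design reproduces the three-part phase-1 structure: Part 1, two
crossover SAD panels of 8 females (6:2 active:placebo re-randomized each
period; doses 180/540/900 and 360/720/900 mg — the second panel's third
period carries the 900-mg repeat through its ordinary periods list); Part
2, two MAD panels (540, 720 mg QD × 7 days; full ECG/PK on Days 1 and 7,
2-h ECGs on Days 3/5, pre-dose PK on Day 5); Part 3, one male single-dose
panel (720, 900 mg). Triplicate ECGs at 0/1/2/4/8/24 h; PK at
0/1/1.5/2/3/4/6/8/12/16/24/48 h; metabolite concentrations only in Parts
1–2. Expected record counts are closed-form functions of the design.

**PK truth.** The parent is an absorption-convolved biexponential — shape
features rather than a named compartmental fit: ka = 0.7/h, fast phase
λ₁ = 0.30/h carrying 75% of the amplitude, terminal phase λ₂ = ln 2 / 9.6 h
(the configured effective half-life), giving tmax ≈ 2–3 h inside the
1.5–4 h design window and a biphasic decline. The metabolite follows
first-order formation/elimination (λ_m = 0.12/h). Both scales are
calibrated at construction so the 45-mg QD steady-state Cmax of each
analyte equals the 0.375 µg/mL therapeutic concentration; doses enter
linearly, so dose proportionality is exact in noise-free mode, and
multiple dosing superposes single-dose curves. Rate collisions (ka equal
to an elimination constant) evaluate through the analytic limit form.
Inter-individual variability is log-normal (CV 30% on scale and ka, 10% on
λ₂, 25% on metabolite scale; means preserved). Values below the 0.005
µg/mL LLOQ are reported as 0 with a BLQ flag, as the assay would.

**QTc truth.** The generative model for post-baseline timepoints is the
analysis model itself on top of a subject/period resting baseline
(N(410, 12²) ms per subject, 4-ms period jitter). Defaults: θ_int = 0.8,
θ_TRT = 2.27 (the value implied by the published prediction table),
θ_DAY = −0.5, θ_rmean = −0.3, circadian effects {1.5, 4.0, 5.0, 3.5, 0.5}
ms at 1/2/4/8/24 h, parent slopes −0.5071 (Day 1) and −0.3622 (Day 7), and,
in the parent+metabolite variant, the published-scale two-analyte slopes.
Random effects: intercept SD 4 ms, slope SD 1.5 ms/(µg/mL), correlation
−0.2; residual SD 5 ms; within-triplicate SD 4 ms. The concentration
slopes are published-scale values; every variance component, the baseline
distribution, the circadian pattern and the heart-rate model (N(63, 7²)
bpm, no drug effect by default) are placeholders chosen as realistic for
healthy volunteers and flagged as such in the emitted truth file. The
Day-1 pre-dose triplicate is generated as resting baseline plus replicate
scatter only; QT is back-computed as QTcF·RR^1/3 so raw records round-trip
through the Fridericia correction exactly.

**What the generator does and does not emulate.** It reproduces the design
(arms, schedules, randomization ratios, metabolite availability), linear
dose-proportional PK with realistic shape, and model-faithful QTc effects.
It does not emulate dropout or missed visits, actual-vs-nominal sampling
time deviations, assay measurement error on concentrations, hysteresis
(effect-compartment delay), or nonlinear exposure–response — so passing
recovery tests demonstrate correctness of the estimator and pipeline under
the stated model, not robustness to those real-data features.

**Model-exact configuration.** `QtcTruth.model_exact()` zeroes the
within-triplicate SD. With replicate scatter present, the measured
baseline carries error (SD δ/√3) that the baseline subtraction injects as
a shared per-period term into every analysis row — a correlation structure
the pre-specified per-subject model does not represent. The Monte-Carlo
recovery and coverage studies therefore use the model-exact configuration,
which makes "data simulated from the analysis model" literally true; the
realistic default (δ = 4 ms) is kept for pipeline demonstrations, where
that extra correlation is a known, documented feature of baseline-anchored
designs rather than an estimator defect.

## Numerical and convention choices

- Rounding of triplicate averages: half away from zero (the SAS
  convention), centralized in one function; applied only where the
  procedure specifies integers.
- Partial triplicates: whatever replicates exist are averaged;
  `n_replicates` is kept for audit.
- Missing RR with HR present: RR = 60/HR, flagged; RR/HR disagreement
  beyond 1% is a data error.
- Correction order: each replicate is corrected to QTcF first, then
  averaged.
- Join key: nominal (protocol) time, matching the class-variable treatment
  of time in the model; Day-1 0-h active rows match the pre-dose PK sample
  (concentration 0), keeping the time-0 class populated in both arms of
  the assembled dataset.
- The parent+metabolite model refuses active rows without a metabolite
  concentration; the pipeline restricts that model to the study parts with
  metabolite assays and skips it (with a logged reason) when none exist.
- Column order and reference levels are frozen so contrast vectors are
  stable across runs; all randomness flows from a single seed
  (SeedSequence-spawned streams), and a run manifest records config hash,
  seed and versions.

## Problem sizes used by the test suite

Unit and property tests run on toy tables and small random datasets (≤5
subjects). The statistical acceptance checks run 1000 full
simulate→assemble→fit→predict replicates at the default 40-subject design
(the first 500 serve the slope-recovery/CI-coverage check, all 1000 the
one-sided upper-bound coverage check), one 400-subject trial for the
fixed-effect consistency check, and 20 random small datasets for the
likelihood-oracle equivalence at 1e-6.

## Known limitations

- Kenward–Roger df are not provided (Satterthwaite/residual only).
- The likelihood is evaluated per subject; crossed or nested grouping
  beyond subject is out of scope.
- BLQ handling is the pre-specified set-to-zero rule; no likelihood-based
  censoring.
- The RR-adequacy flag inherits the naive independence assumption of the
  scatter-plot check it replaces.
- Concentration scenarios treat exposure as fixed known quantities;
  uncertainty in the exposure projection is not propagated.
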