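"""End-to-end pipeline orchestration and report tables.

``run_pipeline`` chains preprocess -> assemble -> fit -> predict -> diagnose
over either supplied CSV inputs or a simulated trial, writes every artifact
(parameter tables, a prediction table in the shape of the published summary,
diagnostics, exclusion log) plus a run manifest, and returns the in-memory
results.  All randomness flows from the configured seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assemble import assemble_dataset
from .diagnostics import (gof, heart_rate_effect, hysteresis_lag,
                          linearity_check, rr_adequacy)
from .ecg import compute_baselines, compute_dqtcf, fridericia_qtc, qtcf_points, read_ecg_csv
from .errors import ConfigurationError
from .model import ModelSpec, fit_with_ladder, parameter_table, slope_summaries
from .predict import build_scenarios, predict
from .simulate import PkTruth, QtcTruth, TrialDesign, simulate_trial

log = logging.getLogger("cqtc")


@dataclass
class ScenarioConfig:
    reference_cmax_parent: float = 0.244     # µg/mL at the reference dose
    reference_cmax_metabolite: float = 0.246
    reference_dose_mg: float = 30.0
    target_dose_mg: float = 45.0
    therapeutic_concentration_override: float = 0.375
    fold_multipliers: tuple = (1, 6, 10)
    one_sided_alpha: float = 0.05


@dataclass
class RunConfig:
    """Either file inputs (ecg/pk/randomization paths) or a simulate block."""

    ecg_path: str = None
    pk_path: str = None
    randomization_path: str = None
    simulate: bool = False
    models: tuple = ("parent", "parent_metabolite")
    scenarios: ScenarioConfig = field(default_factory=ScenarioConfig)
    df_method: str = "satterthwaite"
    input_unit: str = "µg/mL"
    seed: int = 0
    outdir: str = "results/run"
    make_plots: bool = False
    log_level: str = "INFO"

    def __post_init__(self):
        have_files = all(p is not None for p in
                         (self.ecg_path, self.pk_path, self.randomization_path))
        if not (have_files or self.simulate):
            raise ConfigurationError(
                "config needs either all three input paths or simulate=true")

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sc = raw.pop("scenarios", {})
        cfg = RunConfig(**raw)
        if sc:
            cfg.scenarios = ScenarioConfig(**sc)
        return cfg


def render_prediction_table(results: dict) -> tuple[pd.DataFrame, str]:
    """Prediction table: rows scenario x day, per-model prediction and
    upper one-sided 95% CI columns, values formatted to 4 decimals.

    ``results`` maps model name -> list of PredictionResult.  Models absent
    from the mapping are noted in the markdown footer.
    """
    frames = {}
    for model, preds in results.items():
        rows = [{"scenario": p.scenario.label, "day": p.scenario.day,
                 "concentration_ug_ml": p.scenario.cp_parent,
                 f"{model}_prediction_ms": p.ddqtcf_ms,
                 f"{model}_upper95_1sided_ms": p.upper_95_one_sided_ms}
                for p in preds]
        frames[model] = pd.DataFrame(rows)
    if not frames:
        raise ConfigurationError("no prediction results to render")
    keys = ["scenario", "day", "concentration_ug_ml"]
    table = None
    for df in frames.values():
        table = df if table is None else table.merge(df, on=keys, how="outer")
    table = table.sort_values(["concentration_ug_ml", "day"]).reset_index(drop=True)

    show = table.copy()
    for c in show.columns:
        if c.endswith("_ms"):
            show[c] = show[c].map(lambda v: f"{v:.4f}")
    md = show.to_markdown(index=False)
    missing = [m for m in ("parent", "parent_metabolite") if m not in results]
    if missing:
        md += "\n\n*Not fitted: " + ", ".join(missing) + "*"
    return table, md


def _diagnostics_bundle(trial_ecg, assignments, matched, fits):
    """Exploratory + goodness-of-fit statistics as one JSON-able dict."""
    out = {}
    hr = heart_rate_effect(trial_ecg, assignments)
    out["heart_rate"] = {"max_abs_active_vs_placebo_dhr_bpm": hr.max_abs_contrast}
    per_rep = trial_ecg.copy()
    per_rep["qtcf_rep"] = fridericia_qtc(per_rep["qt_ms"].to_numpy(),
                                         per_rep["rr_s"].to_numpy())
    rr = rr_adequacy(per_rep, qtcf_col="qtcf_rep")
    out["rr_adequacy"] = dataclasses.asdict(rr)
    pre = per_rep[(per_rep["day"] == 1) & (per_rep["nominal_time_h"] == 0)]
    out["rr_adequacy_predose"] = dataclasses.asdict(
        rr_adequacy(pre, qtcf_col="qtcf_rep"))
    dosed = matched.merge(
        assignments[["subject_id", "period", "dose_mg"]],
        on=["subject_id", "period"], how="left")
    try:
        lags = hysteresis_lag(dosed[dosed["dose_mg"] > 0])
        out["hysteresis"] = [{k: v for k, v in dataclasses.asdict(h).items()
                              if k != "loop"} for h in lags]
    except Exception as exc:
        out["hysteresis"] = {"error": str(exc)}
    lin = linearity_check(matched)
    out["linearity"] = dataclasses.asdict(lin)
    out["gof"] = {}
    for name, fit in fits.items():
        spec = ModelSpec(name)
        obs = matched
        if name == "parent_metabolite":
            obs = matched[matched["cp_metabolite"].notna() | (matched["trt"] == 0)]
        g = gof(fit, obs, spec)
        out["gof"][name] = {
            "resid_mean_ms": g.resid_mean, "resid_skew": g.resid_skew,
            "time_trend_slope_ms_per_h": g.time_trend_slope,
            "treatment_mean_resid_diff_ms": g.treatment_trend,
            "obs_vs_indiv_pred_corr": g.obs_vs_pred_corr,
        }
    return out


def _plots(outdir, matched, assignments):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    dosed = matched.merge(assignments[["subject_id", "period", "dose_mg"]],
                          on=["subject_id", "period"], how="left")
    fig, axes = plt.subplots(2, 1, figsize=(7, 7), sharex=True)
    for dose, sub in dosed[dosed["dose_mg"] > 0].groupby("dose_mg"):
        prof = sub.groupby("nominal_time_h")[["dqtcf_ms", "cp_parent"]].mean()
        axes[0].plot(prof.index, prof["dqtcf_ms"], marker="o", label=f"{dose:g} mg")
        axes[1].plot(prof.index, prof["cp_parent"], marker="o")
    axes[0].set_ylabel("mean dQTcF (ms)")
    axes[1].set_ylabel("mean concentration (µg/mL)")
    axes[1].set_xlabel("nominal time (h)")
    axes[0].legend(fontsize=8)
    fig.savefig(Path(outdir) / "profiles.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4.5))
    act = matched[matched["trt"] == 1]
    ax.scatter(act["cp_parent"], act["dqtcf_ms"], s=8, alpha=0.4)
    ax.set_xlabel("parent concentration (µg/mL)")
    ax.set_ylabel("dQTcF (ms)")
    fig.savefig(Path(outdir) / "concentration_effect.png", dpi=120)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; writes artifacts under config.outdir.

    Returns a dict with the matched dataset, fits, slope summaries,
    predictions, diagnostics and the manifest.  A model that cannot be fit
    on the data provided (no metabolite concentrations) is skipped with a
    logged reason rather than failing the run.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "load"
    try:
        if config.simulate:
            trial = simulate_trial(TrialDesign.default(), PkTruth(), QtcTruth(),
                                   seed=config.seed)
            ecg_df, pk_df, rand_df = trial.ecg, trial.pk, trial.randomization
            (outdir / "truth.json").write_text(
                json.dumps(trial.truth, indent=2, default=float))
        else:
            ecg_df = read_ecg_csv(config.ecg_path)
            pk_df = pd.read_csv(config.pk_path, float_precision="round_trip")
            rand_df = pd.read_csv(config.randomization_path)

        stage = "preprocess"
        points = qtcf_points(ecg_df)
        baselines = compute_baselines(points)
        dq = compute_dqtcf(points, baselines)
        points.to_csv(outdir / "qtcf_points.csv", index=False)
        pd.DataFrame(
            [{"subject_id": s, "period": p, "baseline_qtcf_ms": v}
             for (s, p), v in sorted(baselines.period_baseline.items())]
        ).to_csv(outdir / "baselines.csv", index=False)

        stage = "assemble"
        matched, exclusions = assemble_dataset(dq, pk_df, rand_df, baselines,
                                               input_unit=config.input_unit)
        matched.to_csv(outdir / "analysis_dataset.csv", index=False)
        exclusions.to_csv(outdir / "exclusions.csv", index=False)

        stage = "fit"
        fits, slopes = {}, {}
        for name in config.models:
            spec = ModelSpec(name)
            obs = matched
            if name == "parent_metabolite":
                if "part" in rand_df.columns:
                    keep = rand_df.loc[rand_df["part"].isin((1, 2)), "subject_id"]
                    obs = matched[matched["subject_id"].isin(set(keep))]
                bad = obs[(obs["trt"] == 1) & (obs["cp_metabolite"].isna())]
                if len(obs) == 0 or len(bad) == len(obs[obs["trt"] == 1]):
                    log.warning("skipping parent_metabolite model: no metabolite "
                                "concentrations available")
                    continue
                obs = obs[(obs["trt"] == 0) | obs["cp_metabolite"].notna()]
            fit = fit_with_ladder(obs, spec, df_method=config.df_method,
                                  seed=config.seed)
            fits[name] = fit
            slopes[name] = slope_summaries(fit, spec)
            parameter_table(fit).to_csv(outdir / f"parameters_{name}.csv",
                                        index=False)
            meta = {"structure_used": fit.structure_used, "loglik": fit.loglik,
                    "converged": fit.converged, "n_obs": fit.n_obs,
                    "n_subjects": fit.n_subjects, "attempts": fit.attempts,
                    "sigma2": fit.sigma2, "df_method": fit.df_method,
                    "re_cov": fit.re_cov.tolist()}
            (outdir / f"model_{name}.json").write_text(
                json.dumps(meta, indent=2, default=str))

        stage = "predict"
        sc = config.scenarios
        predictions = {}
        for name, fit in fits.items():
            spec = ModelSpec(name)
            scen = build_scenarios(
                sc.reference_cmax_parent, sc.reference_cmax_metabolite,
                sc.reference_dose_mg, sc.target_dose_mg, sc.fold_multipliers,
                therapeutic_concentration_override=
                sc.therapeutic_concentration_override)
            if name == "parent":
                scen = [dataclasses.replace(s, cp_metabolite=0.0) for s in scen]
            predictions[name] = [predict(fit, s, spec,
                                         one_sided_alpha=sc.one_sided_alpha,
                                         df_method=config.df_method)
                                 for s in scen]
        if predictions:
            table, md = render_prediction_table(predictions)
            table.to_csv(outdir / "predictions.csv", index=False)
            (outdir / "predictions.md").write_text(md + "\n")

        stage = "diagnose"
        diag = _diagnostics_bundle(ecg_df, rand_df, matched, fits)
        (outdir / "diagnostics.json").write_text(
            json.dumps(diag, indent=2, default=float))
        if config.make_plots:
            _plots(outdir, matched, rand_df)

        stage = "manifest"
        cfg_dict = dataclasses.asdict(config)
        manifest = {
            "config": cfg_dict,
            "config_hash": hashlib.sha256(
                json.dumps(cfg_dict, sort_keys=True, default=str).encode()
            ).hexdigest(),
            "seed": config.seed,
            "versions": {"cqtc": __version__, "numpy": np.__version__,
                         "pandas": pd.__version__},
            "n_matched": int(len(matched)),
            "n_excluded": int(len(exclusions)),
            "models_fit": sorted(fits),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    return {"matched": matched, "exclusions": exclusions, "baselines": baselines,
            "fits": fits, "slopes": slopes, "predictions": predictions,
            "diagnostics": diag, "manifest": manifest}
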