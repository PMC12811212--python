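"""Triplicate ECG processing: Fridericia correction, averaging, baselines, dQTcF.

The raw unit of data is one replicate QT/RR measurement at a nominal time
(three replicates per timepoint by design).  Processing follows the
pre-specified order used in C-QTc practice: each replicate is heart-rate
corrected to QTcF first, then the (up to three) replicate QTcF values at a
timepoint are averaged and rounded to the nearest integer.  The baseline for
a subject-period is the rounded pre-dose Day-1 average; change from baseline
(dQTcF) is taken against that period baseline, so the Day-1 pre-dose point
maps to 0 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    BaselineMissingError,
    DataError,
    InvalidMeasurementError,
    MissingTimepointError,
)

#: Nominal ECG sampling times (hours post dose) used throughout the design.
ECG_NOMINAL_TIMES_H = (0.0, 1.0, 2.0, 4.0, 8.0, 24.0)

ECG_COLUMNS = [
    "subject_id", "part", "panel", "period", "day",
    "nominal_time_h", "replicate", "qt_ms", "rr_s", "hr_bpm",
]

_POINT_KEY = ["subject_id", "period", "day", "nominal_time_h"]


def fridericia_qtc(qt_ms, rr_s):
    """Fridericia-corrected QT: QT / RR^(1/3), RR in seconds.

    Identity at RR = 1 s; strictly decreasing in RR for fixed QT.  Accepts
    scalars or arrays; the result is unrounded.
    """
    qt = np.asarray(qt_ms, dtype=float)
    rr = np.asarray(rr_s, dtype=float)
    if np.any(~np.isfinite(qt)) or np.any(~np.isfinite(rr)):
        raise InvalidMeasurementError("QT and RR must be finite")
    if np.any(qt <= 0) or np.any(rr <= 0):
        raise InvalidMeasurementError("QT and RR must be positive")
    out = qt / np.cbrt(rr)
    return float(out) if np.ndim(qt_ms) == 0 and np.ndim(rr_s) == 0 else out


def round_half_away(x):
    """Round to the nearest integer, halves away from zero.

    Centralised so the whole pipeline shares one rounding convention (the
    convention of the ancestral SAS ROUND function, *not* banker's rounding).
    """
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.floor(np.abs(x) + 0.5)
    return out


def average_triplicate(values) -> int:
    """Average up to three replicate QTcF values and round to integer.

    If fewer than three replicates exist, whatever exists is averaged.
    Permutation invariant; idempotent on integer singletons.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise MissingTimepointError("no replicate values to average")
    if vals.size > 3:
        raise DataError(f"more than 3 replicates supplied ({vals.size})")
    return int(round_half_away(vals.mean()))


def read_ecg_csv(path) -> pd.DataFrame:
    """Read the raw replicate-level ECG CSV (missing values as empty cells)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ECG_COLUMNS if c not in df.columns and c != "panel"]
    if missing:
        raise DataError(f"ECG CSV missing columns: {missing}")
    return df


def _resolve_rr(df: pd.DataFrame) -> pd.DataFrame:
    """Fill missing RR from HR (RR = 60/HR) and check RR/HR consistency (1%)."""
    df = df.copy()
    df["rr_derived"] = False
    have_both = df["rr_s"].notna() & df["hr_bpm"].notna()
    if have_both.any():
        rel = np.abs(df.loc[have_both, "hr_bpm"] - 60.0 / df.loc[have_both, "rr_s"])
        rel = rel / df.loc[have_both, "hr_bpm"]
        bad = rel > 0.01
        if bad.any():
            idx = df.loc[have_both].index[bad][:5].tolist()
            raise DataError(f"RR and HR inconsistent beyond 1% at rows {idx}")
    need = df["rr_s"].isna() & df["hr_bpm"].notna()
    df.loc[need, "rr_s"] = 60.0 / df.loc[need, "hr_bpm"]
    df.loc[need, "rr_derived"] = True
    if df["rr_s"].isna().any():
        n = int(df["rr_s"].isna().sum())
        raise InvalidMeasurementError(f"{n} ECG records have neither RR nor HR")
    return df


def qtcf_points(ecg: pd.DataFrame) -> pd.DataFrame:
    """Per-replicate Fridericia correction, then per-timepoint average+round.

    Returns one row per (subject, period, day, nominal_time) with integer
    ``qtcf_ms`` and the replicate count ``n_replicates`` kept for audit.
    """
    df = _resolve_rr(ecg)
    dup = df.duplicated(subset=_POINT_KEY + ["replicate"])
    if dup.any():
        key = df.loc[dup.idxmax(), _POINT_KEY + ["replicate"]].tolist()
        raise DataError(f"duplicate replicate label at {key}")
    df["qtcf_rep"] = fridericia_qtc(df["qt_ms"].to_numpy(), df["rr_s"].to_numpy())
    grouped = df.groupby(_POINT_KEY, sort=True)["qtcf_rep"]
    out = grouped.agg(["mean", "count"]).reset_index()
    out["qtcf_ms"] = round_half_away(out["mean"].to_numpy()).astype(int)
    out = out.rename(columns={"count": "n_replicates"}).drop(columns=["mean"])
    if (out["n_replicates"] > 3).any():
        raise DataError("more than 3 replicates at a timepoint")
    return out[_POINT_KEY + ["qtcf_ms", "n_replicates"]]


@dataclass
class BaselineSet:
    """Period, individual-mean and grand-mean baselines (all in ms).

    ``period_baseline`` maps (subject_id, period) to the rounded pre-dose
    Day-1 QTcF; ``individual_mean_baseline`` averages a subject's period
    baselines; ``grand_mean_baseline`` averages individual means so every
    subject is weighted equally regardless of how many periods they entered.
    """

    period_baseline: dict = field(default_factory=dict)
    individual_mean_baseline: dict = field(default_factory=dict)
    grand_mean_baseline: float = float("nan")

    def baseline_dev(self, subject_id, period) -> float:
        """Deviation of the subject-period baseline from the grand mean."""
        return self.period_baseline[(subject_id, period)] - self.grand_mean_baseline


def compute_baselines(points: pd.DataFrame) -> BaselineSet:
    """Build the baseline hierarchy from pre-dose Day-1 QTcF points.

    Every (subject, period) present in ``points`` must have a Day-1,
    nominal-time-0 point; otherwise a BaselineMissingError names the first
    offending pair.
    """
    pre = points[(points["day"] == 1) & (points["nominal_time_h"] == 0)]
    period_baseline = {
        (s, p): float(v)
        for s, p, v in pre[["subject_id", "period", "qtcf_ms"]].itertuples(index=False)
    }
    for s, p in points[["subject_id", "period"]].drop_duplicates().itertuples(index=False):
        if (s, p) not in period_baseline:
            raise BaselineMissingError(
                f"no Day-1 pre-dose QTcF point for subject {s!r}, period {p}"
            )
    indiv: dict = {}
    for (s, _p), v in period_baseline.items():
        indiv.setdefault(s, []).append(v)
    individual = {s: float(np.mean(v)) for s, v in indiv.items()}
    grand = float(np.mean(list(individual.values())))
    return BaselineSet(period_baseline, individual, grand)


def compute_dqtcf(points: pd.DataFrame, baselines: BaselineSet) -> pd.DataFrame:
    """Attach dQTcF (change from period baseline) to each QTcF point."""
    df = points.copy()
    try:
        df["dqtcf_ms"] = [
            q - baselines.period_baseline[(s, p)]
            for s, p, q in df[["subject_id", "period", "qtcf_ms"]].itertuples(index=False)
        ]
    except KeyError as exc:  # pragma: no cover - defensive
        raise BaselineMissingError(f"no baseline for subject/period {exc}") from exc
    return df
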