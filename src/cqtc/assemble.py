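"""Assembly of the time-matched C-QTc analysis dataset.

Joins dQTcF points with PK concentrations drawn at the same nominal time and
with the treatment assignment for that subject-period.  Only rows with both
an ECG value and a matching concentration enter the analysis; everything
else is written to an exclusion log so that every ECG point is accounted for
exactly once.  Placebo and below-LLOQ concentrations are set to zero before
matching.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ecg import BaselineSet
from .errors import ConfigurationError, DataError, IntegrityError

#: Assay lower limit of quantification, in µg/mL (5.00 ng/mL).
LLOQ_UG_ML = 0.005

_KEY = ["subject_id", "period", "day", "nominal_time_h"]

_UNIT_TO_UG_ML = {
    "ng/mL": 1e-3,
    "ug/mL": 1.0,
    "µg/mL": 1.0,
}


def normalize_units(samples: pd.DataFrame, input_unit: str) -> pd.DataFrame:
    """Express concentrations in µg/mL (model scale).

    The bioanalytical assay reports ng/mL; the mixed model operates in
    µg/mL.  A single declared unit applies to the whole table.
    """
    if input_unit not in _UNIT_TO_UG_ML:
        raise ConfigurationError(
            f"unknown concentration unit {input_unit!r}; expected one of "
            f"{sorted(_UNIT_TO_UG_ML)}"
        )
    out = samples.copy()
    out["concentration"] = out["concentration"].astype(float) * _UNIT_TO_UG_ML[input_unit]
    out.attrs["unit"] = "µg/mL"
    out.attrs["lloq_ug_ml"] = LLOQ_UG_ML
    return out


def impute_zero(samples: pd.DataFrame, assignments: pd.DataFrame) -> pd.DataFrame:
    """Zero out placebo and BLQ concentrations.

    ``assignments`` has one row per (subject_id, period) with a ``treatment``
    column ("active"/"placebo").  Negative concentrations are a data error.
    """
    if (samples["concentration"].astype(float) < 0).any():
        raise DataError("negative concentration encountered")
    arm = assignments.set_index(["subject_id", "period"])["treatment"]
    out = samples.copy()
    idx = pd.MultiIndex.from_frame(out[["subject_id", "period"]])
    missing = ~idx.isin(arm.index)
    if missing.any():
        key = out.loc[missing, ["subject_id", "period"]].iloc[0].tolist()
        raise DataError(f"no treatment assignment for subject/period {key}")
    is_placebo = (arm.reindex(idx).to_numpy() == "placebo")
    blq = out["blq"].astype(bool).to_numpy()
    out.loc[is_placebo | blq, "concentration"] = 0.0
    return out


def _pivot_pk(samples: pd.DataFrame) -> pd.DataFrame:
    dup = samples.duplicated(subset=_KEY + ["analyte"])
    if dup.any():
        key = samples.loc[dup.idxmax(), _KEY + ["analyte"]].tolist()
        raise IntegrityError(f"duplicate PK sample at key {key}")
    wide = samples.pivot_table(
        index=_KEY, columns="analyte", values="concentration", aggfunc="first"
    ).reset_index()
    wide.columns.name = None
    wide = wide.rename(columns={"parent": "cp_parent", "metabolite": "cp_metabolite"})
    if "cp_parent" not in wide.columns:
        raise DataError("PK table contains no parent-analyte samples")
    if "cp_metabolite" not in wide.columns:
        wide["cp_metabolite"] = np.nan
    return wide


def match(
    points: pd.DataFrame,
    samples: pd.DataFrame,
    assignments: pd.DataFrame,
    baselines: BaselineSet,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inner-join dQTcF points with same-nominal-time concentrations.

    Returns ``(matched, exclusions)``.  ``matched`` has one row per analysis
    observation with columns: the join key, ``day7`` and ``trt`` indicators,
    ``dqtcf_ms``, ``baseline_dev_ms`` (period baseline minus grand mean),
    ``cp_parent``, ``cp_metabolite`` (NaN when unavailable) and a
    ``predose_day1`` flag for the structurally-zero Day-1 pre-dose rows.
    ``exclusions`` lists every ECG point that did not enter, with a reason
    (e.g. the Part-2 Day-3/5 ECGs, which have no matching PK draw).
    """
    dup = points.duplicated(subset=_KEY)
    if dup.any():
        key = points.loc[dup.idxmax(), _KEY].tolist()
        raise IntegrityError(f"duplicate ECG point at key {key}")
    wide = _pivot_pk(samples)

    merged = points.merge(wide, on=_KEY, how="left", indicator=True)
    excluded = merged[merged["_merge"] == "left_only"].copy()
    excluded["reason"] = "no matching concentration"
    matched = merged[merged["_merge"] == "both"].drop(columns=["_merge"]).copy()

    arm = assignments.set_index(["subject_id", "period"])["treatment"]
    idx = pd.MultiIndex.from_frame(matched[["subject_id", "period"]])
    missing = ~idx.isin(arm.index)
    if missing.any():
        key = matched.loc[missing, ["subject_id", "period"]].iloc[0].tolist()
        raise DataError(f"no treatment assignment for subject/period {key}")
    matched["trt"] = (arm.reindex(idx).to_numpy() == "active").astype(int)
    matched["day7"] = (matched["day"] == 7).astype(int)
    matched["baseline_dev_ms"] = [
        baselines.baseline_dev(s, p)
        for s, p in matched[["subject_id", "period"]].itertuples(index=False)
    ]
    # Placebo concentrations are structurally zero for both analytes.
    placebo = matched["trt"] == 0
    matched.loc[placebo, "cp_parent"] = 0.0
    matched.loc[placebo, "cp_metabolite"] = 0.0
    matched["predose_day1"] = ((matched["day"] == 1) & (matched["nominal_time_h"] == 0))

    cols = _KEY + [
        "day7", "trt", "dqtcf_ms", "baseline_dev_ms",
        "cp_parent", "cp_metabolite", "predose_day1", "n_replicates",
    ]
    cols = [c for c in cols if c in matched.columns]
    excl_cols = _KEY + ["qtcf_ms", "dqtcf_ms", "reason"]
    excl_cols = [c for c in excl_cols if c in excluded.columns]
    return matched[cols].reset_index(drop=True), excluded[excl_cols].reset_index(drop=True)


def assemble_dataset(points, samples, assignments, baselines, input_unit="µg/mL"):
    """Convenience wrapper: normalise units, impute zeros, then match."""
    samples = normalize_units(samples, input_unit)
    samples = impute_zero(samples, assignments)
    return match(points, samples, assignments, baselines)
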