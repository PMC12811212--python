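#!/usr/bin/env python
"""Exploratory and goodness-of-fit diagnostics, with plots.

Computes the numeric counterparts of the four pre-model checks (heart-rate
effect, Fridericia adequacy, hysteresis lag, linearity of the
concentration-effect relation) and the post-fit residual summaries, and
draws the profile, scatter and observed-vs-predicted figures.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from cqtc.ecg import read_ecg_csv
from cqtc.model import ModelSpec, fit_with_ladder
from cqtc.pipeline import _diagnostics_bundle, _plots


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/sim"))
    ap.add_argument("--analysis", type=Path, default=Path("results/analysis"))
    ap.add_argument("--out", type=Path, default=Path("results/diagnostics"))
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    ecg = read_ecg_csv(args.data / "ecg.csv")
    rand = pd.read_csv(args.data / "randomization.csv")
    matched = pd.read_csv(args.analysis / "analysis_dataset.csv",
                          float_precision="round_trip")
    fit = fit_with_ladder(matched, ModelSpec("parent"), seed=args.seed)
    diag = _diagnostics_bundle(ecg, rand, matched, {"parent": fit})
    (args.out / "diagnostics.json").write_text(
        json.dumps(diag, indent=2, default=float))
    _plots(args.out, matched, rand)
    print(json.dumps({k: v for k, v in diag.items() if k != "hysteresis"},
                     indent=2, default=float))
    print("hysteresis lags (h):",
          [(h["dose_mg"], h["lag_h"]) for h in diag["hysteresis"]])


if __name__ == "__main__":
    main()
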