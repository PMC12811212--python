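#!/usr/bin/env python
"""Join dQTcF points with time-matched concentrations into the analysis set.

Placebo and below-LLOQ concentrations are set to zero; only rows with both
an ECG value and a same-nominal-time concentration are kept (the Part-2
Day-3/5 ECGs drop out here); every excluded ECG point is logged with its
reason.  Writes analysis_dataset.csv and exclusions.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from cqtc.assemble import assemble_dataset
from cqtc.ecg import compute_baselines


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/sim"))
    ap.add_argument("--pre", type=Path, default=Path("results/preprocessed"))
    ap.add_argument("--out", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    dq = pd.read_csv(args.pre / "qtcf_points.csv", float_precision="round_trip")
    pk = pd.read_csv(args.data / "pk.csv", float_precision="round_trip")
    rand = pd.read_csv(args.data / "randomization.csv")
    baselines = compute_baselines(dq)
    matched, exclusions = assemble_dataset(dq, pk, rand, baselines)
    matched.to_csv(args.out / "analysis_dataset.csv", index=False)
    exclusions.to_csv(args.out / "exclusions.csv", index=False)
    print(f"{len(matched)} matched observations "
          f"({int(matched['predose_day1'].sum())} Day-1 pre-dose rows); "
          f"{len(exclusions)} ECG points excluded "
          f"({exclusions['reason'].value_counts().to_dict()})")


if __name__ == "__main__":
    main()
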