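#!/usr/bin/env python
"""Simulate the three-part phase-1 SAD/MAD trial and write its raw data.

Generates the default design - two crossover SAD panels (180/540/900 and
360/720/900 mg), two 7-day MAD panels (540, 720 mg QD), one single-dose
male panel (720/900 mg); 40 subjects, 6:2 active:placebo per panel -
with triplicate ECGs, scheduled PK draws (metabolite in Parts 1-2 only)
and the generative truth, under results/sim/.
"""

import argparse
from pathlib import Path

from cqtc.simulate import PkTruth, QtcTruth, TrialDesign, simulate_trial


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/sim"))
    args = ap.parse_args()

    design = TrialDesign.default()
    trial = simulate_trial(design, PkTruth(), QtcTruth(), seed=args.seed)
    trial.write(args.out)
    n_active = (trial.randomization["treatment"] == "active").sum()
    print(f"wrote {args.out}/: {len(trial.ecg)} ECG replicates "
          f"({design.expected_ecg_rows()} by design), "
          f"{len(trial.pk)} PK samples, "
          f"{trial.randomization['subject_id'].nunique()} subjects "
          f"({n_active} active subject-periods)")


if __name__ == "__main__":
    main()
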