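#!/usr/bin/env python
"""Build the study-like synthetic cohort.

Draws 58 virtual surgical patients matching the published demographics and
simulates 176 vancomycin concentrations from the final population model
(one dose each, 0.5-h infusion, samples on a first-dose TDM grid).  Writes
the event dataset and the ground-truth sidecar used by the later stages.
"""

import json
from pathlib import Path

import numpy as np

from vancopk.datasets import write_dataset
from vancopk.synthetic import make_study_dataset

SEED = 20210721
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    ds, truth = make_study_dataset(seed=SEED)
    write_dataset(ds, OUT / "cohort.csv")
    with open(OUT / "cohort_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)

    frame = ds.frame
    per_subject = frame.groupby("ID").first()
    obs = frame[frame["EVID"] == 0]
    print(f"cohort: {ds.subject_count} subjects, {ds.observation_count} observations")
    for col in ("AGE", "WT", "SCR", "CRCL"):
        s = per_subject[col]
        print(f"  {col:>4}: median {s.median():7.2f}  range {s.min():7.2f}-{s.max():7.2f}")
    n_f = (per_subject["SEX"] == "female").sum()
    print(f"  sex : {len(per_subject) - n_f} male / {n_f} female")
    print(f"  DV  : median {obs['DV'].median():.1f}  range {obs['DV'].min():.1f}-{obs['DV'].max():.1f} mg/L")
    print(f"wrote {OUT / 'cohort.csv'} and ground-truth sidecar")


if __name__ == "__main__":
    main()
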