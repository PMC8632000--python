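#!/usr/bin/env python
"""Renal-function-based dose tailoring at steady state.

Simulates 1,000 virtual patients per creatinine-clearance stratum (20, 60,
100, 140 ml/min) under the final model: first the common 1,000 mg q12h
regimen, then a tailored-dose search over 200-1,400 mg maximizing the
fraction of troughs within the 10-20 mg/l target range.  Writes the
trough-summary table analogous to the published dosing table.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from vancopk.dosing import DoseRegimen, simulate_troughs, tailor_dose
from vancopk.model import final_model

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20210721


def main() -> None:
    model = final_model()
    candidates = np.arange(200.0, 1500.0, 100.0)
    rows = []
    for crcl in (20.0, 60.0, 100.0, 140.0):
        common = simulate_troughs(model, crcl, DoseRegimen(1000.0), n=1000, seed=SEED)
        selected, table = tailor_dose(model, crcl, candidates, n=1000, seed=SEED)
        tailored = table.set_index("dose_mg").loc[selected]
        rows.append(
            {
                "crcl_ml_min": crcl,
                "common_dose_mg": 1000,
                "common_trough_mean": round(common.trough_mean, 1),
                "common_trough_sd": round(common.trough_sd, 2),
                "common_fraction_in_ttcr": round(common.fraction_in_ttcr, 3),
                "tailored_dose_mg": selected,
                "tailored_trough_mean": round(tailored["trough_mean"], 1),
                "tailored_trough_sd": round(tailored["trough_sd"], 2),
                "tailored_fraction_in_ttcr": round(tailored["fraction_in_ttcr"], 3),
            }
        )
    frame = pd.DataFrame(rows)
    frame.to_csv(OUT / "dosing_table.csv", index=False)
    print(frame.to_string(index=False))
    print(
        "\nA fixed 1,000 mg q12h overshoots the 10-20 mg/l trough window in "
        "renally impaired strata; the tailored doses keep most patients in range."
    )


if __name__ == "__main__":
    main()
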