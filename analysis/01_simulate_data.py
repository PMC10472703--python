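#!/usr/bin/env python
"""Generate the synthetic study data every later stage consumes.

Produces, under results/: a scotopic ERG intensity series spanning the
four light zones (epochs.csv), a longitudinal two-group glucose cohort
with the diabetic-inclusion flag applied (cohort.csv), and three-phase
oxygen-consumption traces for control and diabetic wells (ocr.csv).
"""

from pathlib import Path

import pandas as pd

from ergflux.io import write_epochs
from ergflux.synth import (
    CohortDesign,
    ERGSimParams,
    OCRSimParams,
    inclusion_flags,
    simulate_cohort,
    simulate_intensity_series,
    simulate_ocr_trace,
    split_seed,
)

SEED = 20230901
OUT = Path(__file__).resolve().parent.parent / "results"
INTENSITIES = [-4.32, -3.3, -2.8, -2.3, -1.8, -1.3, -0.8, 0.3, 1.3]


def main() -> None:
    OUT.mkdir(exist_ok=True)

    params = ERGSimParams()  # defaults: 2 kHz, 40-sweep averaging
    epochs = simulate_intensity_series(params, INTENSITIES, seed=SEED)
    for i, e in enumerate(epochs):
        e.meta["epoch_id"] = f"epoch{i:03d}"
    write_epochs(epochs, OUT / "epochs.csv")
    print(f"simulated {len(epochs)} epochs across zones "
          f"{sorted({e.meta['zone'] for e in epochs})} -> results/epochs.csv")

    design = CohortDesign(
        group_sizes={"db/+": 14, "db/db": 11},
        weeks=[9, 13, 17, 25],
        targets={
            "glucose": {   # mmol/L, control normoglycemic vs diabetic
                "db/+": {9: (7.0, 0.2), 13: (7.1, 0.2), 17: (7.2, 0.2),
                         25: (7.3, 0.2)},
                "db/db": {9: (20.0, 1.0), 13: (24.0, 1.2), 17: (26.0, 1.2),
                          25: (27.0, 1.3)},
            }
        },
    )
    cohort = simulate_cohort(design, seed=split_seed(SEED, 1))
    flags = inclusion_flags(cohort)
    cohort.to_csv(OUT / "cohort.csv", index=False)
    print(f"cohort: {len(flags)} animals, "
          f"{int(flags.sum())} meet the >= 13.9 mmol/L inclusion rule "
          "-> results/cohort.csv")

    traces = []
    for i, (group, basal, fccp) in enumerate(
        [("db/+", 122.76, 147.87), ("db/db", 75.29, 94.41)]
    ):
        df = simulate_ocr_trace(
            OCRSimParams(basal_level=basal + 25, fccp_plateau=fccp + 25,
                         nonmito_level=25.0, noise_sd=3.0),
            seed=split_seed(SEED, 10 + i),
            well_id=f"{group}-w1",
        )
        df["group"] = group
        traces.append(df)
    pd.concat(traces, ignore_index=True).to_csv(OUT / "ocr.csv", index=False)
    print("OCR traces for db/+ and db/db wells -> results/ocr.csv")


if __name__ == "__main__":
    main()
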