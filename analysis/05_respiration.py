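#!/usr/bin/env python
"""Derive mitochondrial respiration parameters from the OCR traces.

Reads results/ocr.csv (basal -> FCCP -> rotenone/antimycin-A phases per
well), computes basal, maximal, spare and non-mitochondrial respiration
per well, and writes results/respiration.csv.
"""

from pathlib import Path

import pandas as pd

from ergflux.flux import compute_respiration_params, segment_phases

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ocr = pd.read_csv(OUT / "ocr.csv")
    rows = []
    for well, sub in ocr.groupby("well_id"):
        params = compute_respiration_params(segment_phases(sub))
        rows.append(
            {
                "well_id": well,
                "group": sub["group"].iloc[0],
                "basal_pmol_min": params.basal,
                "maximal_pmol_min": params.maximal,
                "spare_pmol_min": params.spare,
                "nonmito_pmol_min": params.nonmito,
                "flags": ";".join(sorted(params.flags)),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "respiration.csv", index=False)
    print(df.to_string(index=False))
    print("\nper-well respiration parameters -> results/respiration.csv")


if __name__ == "__main__":
    main()
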