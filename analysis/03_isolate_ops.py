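#!/usr/bin/env python
"""Isolate oscillatory potentials at +0.3 log cd*s/m^2 and measure them.

Applies the hard 65-300 Hz FFT band-pass to the OP recording epoch,
detects the first four major wavelets, and writes per-wavelet peak
times, implicit times and peak-to-trough amplitudes plus their sum to
results/ops.csv.
"""

from pathlib import Path

import pandas as pd

from ergflux.features import baseline_correct
from ergflux.io import read_epochs
from ergflux.ops import detect_op_wavelets, spectral_bandpass, sum_op_amplitudes

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    epochs = read_epochs(OUT / "epochs.csv")
    epoch = min(epochs, key=lambda e: abs(e.intensity_log - 0.3))
    filtered = spectral_bandpass(baseline_correct(epoch), 65.0, 300.0)
    res = detect_op_wavelets(filtered, search_window_ms=(10.0, 100.0), k=4)
    df = pd.DataFrame(
        {
            "wavelet": range(1, len(res.peak_times_ms) + 1),
            "peak_time_ms": res.peak_times_ms,
            "implicit_ms": res.implicit_ms,
            "amplitude_uv": res.amplitudes_uv,
        }
    )
    df["sum_amp_uv"] = sum_op_amplitudes(res)
    df.to_csv(OUT / "ops.csv", index=False)
    print(df.to_string(index=False))
    print(f"\nsum of the first {len(res.amplitudes_uv)} OP amplitudes: "
          f"{res.sum_amp_uv:.1f} uV -> results/ops.csv")


if __name__ == "__main__":
    main()
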