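"""a-wave, b-wave and pSTR feature extraction from ERG epochs.

Measurement conventions follow standard full-field ERG practice: the
a-wave amplitude is the depth of the trough below the pre-stimulus
baseline; the b-wave amplitude is measured trough-to-peak (from the
a-trough) when a measurable a-wave is present and baseline-to-peak
otherwise; the pSTR amplitude is the positive excursion in a late
window at rod-threshold intensities. Implicit times run from stimulus
onset to the respective extremum. A gentle low-pass (default 60 Hz
Butterworth, zero-phase) suppresses the 65-300 Hz oscillatory
potentials before peak localization so they cannot capture the b-peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

from ergflux.epoch import ERGEpoch


class WindowError(ValueError):
    """Raised when a measurement window does not fit the epoch."""


@dataclass(frozen=True)
class FeatureWindows:
    """Search windows (ms from stimulus onset) and measurement options.

    ``b_reference``: "trough" (b measured from the a-trough),
    "baseline", or "auto" (trough when the a-wave clears the noise
    gate, else baseline). ``noise_floor_uv`` is the minimum a-wave
    amplitude treated as real when the pre-stimulus trace is silent.
    """

    a_window: tuple[float, float] = (3.0, 50.0)
    b_window: tuple[float, float] = (20.0, 150.0)
    pstr_window: tuple[float, float] = (80.0, 200.0)
    smooth: bool = True
    smooth_cutoff_hz: float = 60.0
    b_reference: str = "auto"
    noise_gate_sds: float = 3.0
    noise_floor_uv: float = 1.0


@dataclass
class WaveformFeatures:
    """Extracted ERG component amplitudes (uV) and implicit times (ms)."""

    a_amp: float = 0.0
    a_implicit_ms: float = float("nan")
    b_amp: float = 0.0
    b_implicit_ms: float = float("nan")
    pstr_amp: float = float("nan")
    pstr_implicit_ms: float = float("nan")
    baseline_uv: float = 0.0
    flags: set[str] = field(default_factory=set)


def baseline_correct(epoch: ERGEpoch, min_pre_ms: float = 10.0) -> ERGEpoch:
    """Subtract the mean of the pre-stimulus window from the whole trace."""
    pre = epoch.pre_stim
    if epoch.time_ms[pre].size * epoch.dt_ms < min_pre_ms:
        raise WindowError(
            f"need >= {min_pre_ms} ms of pre-stimulus baseline"
        )
    offset = float(epoch.voltage_uv[pre].mean())
    return epoch.with_voltage(epoch.voltage_uv - offset, baseline_offset_uv=offset)


def _smooth(epoch: ERGEpoch, cutoff_hz: float) -> np.ndarray:
    nyq = epoch.fs_hz / 2.0
    if cutoff_hz >= nyq:
        return epoch.voltage_uv.copy()
    b, a = butter(4, cutoff_hz / nyq, btype="low")
    return filtfilt(b, a, epoch.voltage_uv)


def _window_indices(epoch: ERGEpoch, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    if lo >= hi:
        raise WindowError(f"empty window {window}")
    idx = np.flatnonzero((epoch.time_ms >= lo) & (epoch.time_ms <= hi))
    if idx.size == 0:
        raise WindowError(f"window {window} ms lies outside the epoch")
    return idx


def _prestim_sd(epoch: ERGEpoch) -> float:
    pre = epoch.voltage_uv[epoch.pre_stim]
    return float(pre.std(ddof=0)) if pre.size else 0.0


def measure_ab_waves(
    epoch: ERGEpoch, windows: FeatureWindows = FeatureWindows()
) -> WaveformFeatures:
    """Measure a- and b-wave amplitudes and implicit times.

    Expects a baseline-corrected epoch. Flat traces yield zero
    amplitudes with a ``"flat"`` flag rather than an error.
    """
    feats = WaveformFeatures()
    v = _smooth(epoch, windows.smooth_cutoff_hz) if windows.smooth else epoch.voltage_uv
    a_idx = _window_indices(epoch, windows.a_window)
    b_idx = _window_indices(epoch, windows.b_window)

    span = float(np.ptp(v[np.concatenate([a_idx, b_idx])]))
    if span < 1e-12:
        feats.flags.add("flat")
        return feats

    i_a = a_idx[int(np.argmin(v[a_idx]))]
    a_trough = float(v[i_a])
    feats.a_amp = max(0.0, -a_trough)
    feats.a_implicit_ms = float(epoch.time_ms[i_a])
    if a_trough >= 0:
        feats.flags.add("no-a-trough")

    i_b = b_idx[int(np.argmax(v[b_idx]))]
    b_peak = float(v[i_b])
    feats.b_implicit_ms = float(epoch.time_ms[i_b])

    gate = max(
        windows.noise_gate_sds * _prestim_sd(epoch), windows.noise_floor_uv
    )
    use_trough = windows.b_reference == "trough" or (
        windows.b_reference == "auto" and feats.a_amp >= gate
    )
    if use_trough and a_trough < 0:
        feats.b_amp = max(0.0, b_peak - a_trough)
    else:
        feats.b_amp = max(0.0, b_peak)
        feats.flags.add("b-from-baseline")
    if b_peak <= 0:
        feats.flags.add("no-b-peak")
    return feats


def measure_pstr(
    epoch: ERGEpoch, windows: FeatureWindows = FeatureWindows()
) -> WaveformFeatures:
    """Measure the positive scotopic threshold response.

    The pSTR amplitude is the maximum of the (baseline-corrected) trace
    in the pSTR window, clamped at zero: a window containing only
    negative deflections reports amplitude 0 with a flag.
    """
    feats = WaveformFeatures()
    v = _smooth(epoch, windows.smooth_cutoff_hz) if windows.smooth else epoch.voltage_uv
    idx = _window_indices(epoch, windows.pstr_window)
    i_p = idx[int(np.argmax(v[idx]))]
    peak = float(v[i_p])
    feats.pstr_amp = max(0.0, peak)
    feats.pstr_implicit_ms = float(epoch.time_ms[i_p])
    if peak <= 0:
        feats.flags.add("no-pstr-peak")
    return feats


def average_sweeps(epochs: list[ERGEpoch]) -> ERGEpoch:
    """Pointwise average of sweeps recorded at the same intensity."""
    if not epochs:
        raise ValueError("no epochs to average")
    first = epochs[0]
    for e in epochs[1:]:
        if e.time_ms.size != first.time_ms.size or not np.allclose(
            e.time_ms, first.time_ms, rtol=0, atol=1e-9
        ):
            raise ValueError("epochs have mismatched time grids")
        if e.intensity_log != first.intensity_log:
            raise ValueError("epochs have mismatched stimulus intensities")
    mean_v = np.mean([e.voltage_uv for e in epochs], axis=0)
    return first.with_voltage(mean_v, n_averaged=len(epochs))
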