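"""Oscillatory-potential isolation and wavelet quantification.

OPs are isolated exactly as the recording protocol prescribes: the raw
epoch is taken to the frequency domain with an FFT, every spectral
component whose frequency lies outside the 65-300 Hz band is zeroed
(hard rectangular mask, band edges retained), and the inverse FFT
reconstructs the OP waveform in the time domain. Wavelets are then
measured on the filtered trace: implicit time from stimulus onset to
each peak, amplitude from the peak to the adjacent trough, and the
first four major wavelets summed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, get_window

from ergflux.epoch import ERGEpoch

#: OP spectral band in Hz
DEFAULT_BAND = (65.0, 300.0)


class NoPeaksError(RuntimeError):
    """Raised when no qualifying OP wavelet is found."""


@dataclass
class OPResult:
    """Isolated OP waveform and per-wavelet measurements.

    ``amplitudes_uv[i]`` is peak-to-adjacent-trough; ``sum_amp_uv`` is
    the sum over the retained (first <= 4) wavelets.
    """

    filtered_uv: np.ndarray
    peak_times_ms: list[float]
    implicit_ms: list[float]
    amplitudes_uv: list[float]
    sum_amp_uv: float
    band_hz: tuple[float, float]
    flags: set[str] = field(default_factory=set)


def spectral_bandpass(
    epoch: ERGEpoch,
    lo_hz: float = DEFAULT_BAND[0],
    hi_hz: float = DEFAULT_BAND[1],
    taper: str | None = None,
) -> ERGEpoch:
    """Hard FFT band-pass: zero every bin with |f| outside [lo, hi].

    Band edges are inclusive (bins at exactly lo or hi survive). The
    mask is applied on the native frequency grid with no zero-padding;
    ``taper`` optionally names a window (e.g. ``"hann"``) for a
    smoothed mask edge, default off.
    """
    if lo_hz >= hi_hz:
        raise ValueError(f"need lo < hi, got ({lo_hz}, {hi_hz})")
    if lo_hz <= 0:
        raise ValueError("lo_hz must be > 0")
    nyquist = epoch.fs_hz / 2.0
    if hi_hz > nyquist:
        raise ValueError(f"hi_hz {hi_hz} exceeds Nyquist {nyquist}")
    n = epoch.n_samples
    if n < 8:
        raise ValueError("epoch too short to filter (need >= 8 samples)")

    v = epoch.voltage_uv
    if taper is not None:
        v = v * get_window(taper, n)
    spectrum = np.fft.fft(v)
    freqs = np.abs(np.fft.fftfreq(n, d=1.0 / epoch.fs_hz))
    mask = (freqs >= lo_hz) & (freqs <= hi_hz)
    filtered = np.fft.ifft(spectrum * mask)

    norm = np.linalg.norm(v)
    if norm > 0 and np.linalg.norm(filtered.imag) > 1e-9 * norm:
        raise AssertionError("inverse FFT left a non-negligible imaginary part")
    return epoch.with_voltage(filtered.real, op_band_hz=(lo_hz, hi_hz))


def detect_op_wavelets(
    filtered: ERGEpoch,
    search_window_ms: tuple[float, float] = (10.0, 100.0),
    k: int = 4,
    prominence_uv: float | None = None,
    noise_gate_sds: float = 3.0,
    trough: str = "following",
) -> OPResult:
    """Locate and measure the first ``k`` major OP wavelets.

    Local maxima inside the search window with prominence above the
    threshold (default ``noise_gate_sds`` times the filtered
    pre-stimulus sd) are taken in time order and the first ``k`` kept.
    Implicit time is the peak time from stimulus onset. Amplitude is
    peak minus the adjacent trough — the next local minimum after the
    peak by default (``trough="following"``); if none follows, or with
    ``trough="preceding"``, the preceding minimum is used and the
    result flagged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if trough not in ("following", "preceding"):
        raise ValueError("trough must be 'following' or 'preceding'")
    v = filtered.voltage_uv
    t = filtered.time_ms
    lo, hi = search_window_ms
    if lo >= hi:
        raise ValueError(f"empty search window {search_window_ms}")
    in_window = (t >= lo) & (t <= hi)
    if not np.any(in_window):
        raise ValueError(f"search window {search_window_ms} outside epoch")

    if prominence_uv is None:
        pre = v[filtered.pre_stim]
        sd = float(pre.std(ddof=0)) if pre.size else 0.0
        prominence_uv = max(noise_gate_sds * sd, 1e-9)

    peaks, _ = find_peaks(v, prominence=prominence_uv)
    troughs, _ = find_peaks(-v)
    peaks = [p for p in peaks if in_window[p]]
    if not peaks:
        raise NoPeaksError(
            f"no OP peak with prominence >= {prominence_uv:.3g} uV "
            f"in {search_window_ms} ms"
        )

    flags: set[str] = set()
    if len(peaks) < k:
        flags.add("partial")
    peaks = peaks[:k]

    troughs = np.asarray(troughs)
    peak_times, implicit, amps = [], [], []
    for p in peaks:
        following = troughs[troughs > p]
        preceding = troughs[troughs < p]
        if trough == "following" and following.size:
            tr = following[0]
        elif preceding.size:
            tr = preceding[-1]
            if trough == "following":
                flags.add("preceding-trough")
        elif following.size:
            tr = following[0]
        else:
            flags.add("no-trough")
            tr = None
        peak_times.append(float(t[p]))
        implicit.append(float(t[p]))  # stimulus onset is t = 0
        amps.append(float(v[p] - (v[tr] if tr is not None else 0.0)))

    return OPResult(
        filtered_uv=v,
        peak_times_ms=peak_times,
        implicit_ms=implicit,
        amplitudes_uv=amps,
        sum_amp_uv=float(np.sum(amps)),
        band_hz=filtered.meta.get("op_band_hz", DEFAULT_BAND),
        flags=flags,
    )


def sum_op_amplitudes(result: OPResult, k: int = 4) -> float:
    """Sum of the first (up to) ``k`` wavelet amplitudes in microvolts."""
    if not result.amplitudes_uv:
        raise ValueError("OP result contains no amplitudes")
    return float(np.sum(result.amplitudes_uv[:k]))
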