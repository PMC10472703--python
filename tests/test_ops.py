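"""OP isolation: hard FFT band-pass properties and wavelet quantification."""

import numpy as np
import pytest
from scipy.signal import find_peaks

from ergflux.epoch import ERGEpoch, make_time_grid
from ergflux.ops import (
    NoPeaksError,
    detect_op_wavelets,
    spectral_bandpass,
    sum_op_amplitudes,
    OPResult,
)
from ergflux.synth import ERGSimParams, simulate_erg_epoch


def _epoch(v, fs=1000.0, pre_ms=100.0):
    t = make_time_grid(fs, v.size / fs * 1000.0, pre_ms)
    return ERGEpoch(t, v, 0.3, fs)


def _sine(freq_hz, fs=1000.0, n=1000):
    # n/fs spans integer cycles for integer freq_hz when fs divides n*freq
    return np.sin(2 * np.pi * freq_hz * np.arange(n) / fs)


class TestSpectralBandpass:
    def test_dc_is_rejected(self):
        out = spectral_bandpass(_epoch(np.ones(1000))).voltage_uv
        assert np.abs(out).max() < 1e-9

    @pytest.mark.parametrize("freq", [65.0, 100.0, 300.0])
    def test_passband_sinusoid_preserved(self, freq):
        v = _sine(freq)
        out = spectral_bandpass(_epoch(v)).voltage_uv
        assert np.abs(out - v).max() < 1e-9

    @pytest.mark.parametrize("freq", [30.0, 400.0])
    def test_stopband_sinusoid_suppressed(self, freq):
        out = spectral_bandpass(_epoch(_sine(freq))).voltage_uv
        assert np.abs(out).max() < 1e-9

    def test_passband_matches_direct_dft_reconstruction(self):
        # independent oracle: project onto the retained Fourier bins directly
        rng = np.random.default_rng(0)
        v = rng.normal(size=512)
        fs, n = 1000.0, 512
        k = np.fft.fftfreq(n, d=1 / fs)
        coef = np.fft.fft(v)
        keep = (np.abs(k) >= 65.0) & (np.abs(k) <= 300.0)
        oracle = (coef[keep] @ np.exp(2j * np.pi * np.outer(
            k[keep] / fs, np.arange(n))) / n).real
        out = spectral_bandpass(_epoch(v, fs=fs)).voltage_uv
        assert np.abs(out - oracle).max() < 1e-9

    def test_linearity(self, rng):
        x, y = rng.normal(size=1000), rng.normal(size=1000)
        fx = spectral_bandpass(_epoch(x)).voltage_uv
        fy = spectral_bandpass(_epoch(y)).voltage_uv
        fxy = spectral_bandpass(_epoch(2.0 * x - 3.0 * y)).voltage_uv
        assert np.abs(fxy - (2.0 * fx - 3.0 * fy)).max() < 1e-9

    def test_idempotence(self, rng):
        e = _epoch(rng.normal(size=1000))
        once = spectral_bandpass(e)
        twice = spectral_bandpass(once)
        assert np.abs(twice.voltage_uv - once.voltage_uv).max() < 1e-9

    def test_energy_never_increases(self, rng):
        for _ in range(5):
            v = rng.normal(size=777)
            out = spectral_bandpass(_epoch(v)).voltage_uv
            assert np.sum(out**2) <= np.sum(v**2) + 1e-9

    def test_band_validation(self):
        e = _epoch(np.zeros(100), pre_ms=10.0)
        with pytest.raises(ValueError):
            spectral_bandpass(e, 65.0, 600.0)  # above Nyquist at 1 kHz
        with pytest.raises(ValueError):
            spectral_bandpass(e, 300.0, 65.0)
        with pytest.raises(ValueError):
            spectral_bandpass(e, 0.0, 300.0)


class TestDetectWavelets:
    def test_triangle_peak_to_adjacent_trough(self):
        # rise to +10, fall to -4: amplitude forced to 14
        v = np.zeros(1000)
        v[200:211] = np.linspace(0, 10, 11)
        v[211:222] = np.linspace(10, -4, 12)[1:]
        v[222:233] = np.linspace(-4, 0, 12)[1:]
        res = detect_op_wavelets(
            _epoch(v), search_window_ms=(50.0, 150.0), k=1, prominence_uv=1.0
        )
        assert res.amplitudes_uv[0] == pytest.approx(14.0, abs=1e-9)

    def test_all_zero_trace_raises_no_peaks(self):
        with pytest.raises(NoPeaksError):
            detect_op_wavelets(_epoch(np.zeros(1000)))

    def test_gabor_train_peak_times_recovered(self):
        fs = 2000.0
        t = make_time_grid(fs, 350.0, 50.0)
        truth_times = np.array([18.0, 27.0, 36.0, 45.0])
        amps = np.array([100.0, 85.0, 70.0, 55.0])
        v = np.zeros_like(t)
        for tk, ak in zip(truth_times, amps):
            v += ak * np.exp(-((t - tk) ** 2) / (2 * 4.5**2)) * np.cos(
                2e-3 * np.pi * 111.0 * (t - tk)
            )
        res = detect_op_wavelets(ERGEpoch(t, v, 0.3, fs), k=4)
        assert len(res.peak_times_ms) == 4
        assert np.abs(np.array(res.peak_times_ms) - truth_times).max() <= 1000.0 / fs
        assert res.implicit_ms == res.peak_times_ms  # onset at t = 0
        assert list(res.peak_times_ms) == sorted(res.peak_times_ms)

    def test_partial_result_flagged_when_fewer_than_k(self):
        fs = 2000.0
        t = make_time_grid(fs, 350.0, 50.0)
        v = 50.0 * np.exp(-((t - 30.0) ** 2) / (2 * 4.5**2)) * np.cos(
            2e-3 * np.pi * 110.0 * (t - 30.0)
        )
        res = detect_op_wavelets(ERGEpoch(t, v, 0.3, fs), k=4, prominence_uv=10.0)
        assert len(res.amplitudes_uv) < 4
        assert "partial" in res.flags

    def test_preceding_trough_convention(self):
        fs = 2000.0
        t = make_time_grid(fs, 350.0, 50.0)
        v = 50.0 * np.exp(-((t - 30.0) ** 2) / (2 * 4.5**2)) * np.cos(
            2e-3 * np.pi * 110.0 * (t - 30.0)
        )
        e = ERGEpoch(t, v, 0.3, fs)
        following = detect_op_wavelets(e, k=1, prominence_uv=10.0)
        preceding = detect_op_wavelets(e, k=1, prominence_uv=10.0, trough="preceding")
        # symmetric wavelet: both conventions see the same trough depth
        assert preceding.amplitudes_uv[0] == pytest.approx(
            following.amplitudes_uv[0], rel=1e-6
        )


class TestSumAmplitudes:
    def test_reported_component_sum(self):
        res = OPResult(
            filtered_uv=np.zeros(1),
            peak_times_ms=[15, 24, 33, 42],
            implicit_ms=[15, 24, 33, 42],
            amplitudes_uv=[126.31, 174.63, 113.63, 31.80],
            sum_amp_uv=446.37,
            band_hz=(65, 300),
        )
        assert sum_op_amplitudes(res) == pytest.approx(446.37, abs=1e-9)

    def test_single_amplitude(self):
        res = OPResult(np.zeros(1), [10], [10], [42.0], 42.0, (65, 300))
        assert sum_op_amplitudes(res) == 42.0

    def test_empty_errors(self):
        res = OPResult(np.zeros(1), [], [], [], 0.0, (65, 300))
        with pytest.raises(ValueError):
            sum_op_amplitudes(res)


class TestEndToEnd:
    def test_simulated_op_recovery(self, clean_params):
        e = simulate_erg_epoch(clean_params, 0.3, seed=1)
        filtered = spectral_bandpass(e)
        res = detect_op_wavelets(filtered)

        assert len(res.peak_times_ms) == clean_params.n_wavelets
        truth_times = clean_params.op_peak_times_ms()
        assert np.abs(
            np.array(res.peak_times_ms) - truth_times
        ).max() <= 1000.0 / clean_params.fs_hz

        # independent amplitude oracle: peak-to-following-trough of the
        # pure (unfiltered) wavelet train at the known peak positions
        t = e.time_ms
        sigma = 0.5 * 1000.0 / clean_params.op_freq_hz
        pure = np.zeros_like(t)
        for tk, ak in zip(truth_times, clean_params.op_amplitudes(0.3)):
            pure += ak * np.exp(-((t - tk) ** 2) / (2 * sigma**2)) * np.cos(
                2e-3 * np.pi * clean_params.op_freq_hz * (t - tk)
            )
        troughs, _ = find_peaks(-pure)
        truth_amps = []
        for tk in truth_times:
            i = int(np.argmin(np.abs(t - tk)))
            j = int(np.argmax(pure[max(i - 5, 0): i + 6])) + max(i - 5, 0)
            truth_amps.append(pure[j] - pure[troughs[troughs > j][0]])
        assert np.array(res.amplitudes_uv) == pytest.approx(
            np.array(truth_amps), rel=0.10
        )
        assert res.sum_amp_uv == pytest.approx(sum(res.amplitudes_uv), abs=1e-9)
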