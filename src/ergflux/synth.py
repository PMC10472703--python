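"""Synthetic electrophysiology and bioenergetics data.

Every downstream stage of the pipeline (feature extraction, OP
isolation, Naka-Rushton fitting, respiration parameters, statistics)
is exercised against data from this module, for which the ground truth
is known exactly.

The ERG waveform model composes minimal smooth shapes with controllable
peak times and amplitudes:

* a-wave — negative gamma-density-like lobe, trough at ``a_peak_ms``,
  present at zone-3/4 intensities (where photoreceptor responses are
  measurable);
* b-wave — positive gamma-density-like transient peaking at
  ``b_peak_ms``; its amplitude follows the Naka-Rushton saturating
  function of linear flash intensity, with asymptote ``b_amp_max``
  (the true Bmax);
* oscillatory potentials — ``n_wavelets`` Gabor wavelets at
  ``op_freq_hz`` riding the b-wave rising limb, one per carrier period
  starting at ``op_onset_ms``, each scaled by ``op_gain`` times the
  b-wave amplitude with a mild per-wavelet decay;
* pSTR — a small, slow positive lobe that dominates at zone-1
  (rod-threshold) intensities;
* noise — i.i.d. Gaussian with sd ``noise_sd / sqrt(n_sweeps)``,
  emulating sweep averaging.

All stimulus-driven components are identically zero before stimulus
onset and below the detection-threshold intensity. Every generator is
a pure function of (parameters, seed).

Seed splitting
--------------
Collections derive the seed of element ``i`` from the master seed as
``SeedSequence([master_seed, i])`` (see :func:`split_seed`), so lists
are reproducible element-wise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ergflux.calibration import ZoneBoundaries, DEFAULT_ZONES, classify_light_zone
from ergflux.epoch import ERGEpoch, make_time_grid
from ergflux.nakarushton import naka_rushton


class InvalidParamsError(ValueError):
    """Raised when simulation parameters violate their invariants."""


def split_seed(master_seed: int, index: int) -> int:
    """Deterministic child seed for element ``index`` of a collection.

    Uses ``numpy.random.SeedSequence([master_seed, index])`` and keeps
    the result below 2**31.
    """
    state = np.random.SeedSequence([int(master_seed), int(index)])
    return int(state.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


# --------------------------------------------------------------------------
# ERG epochs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ERGSimParams:
    """Ground-truth parameters of the synthetic scotopic ERG.

    Amplitudes in microvolts, times in ms, frequencies in Hz. Defaults
    follow typical murine scotopic timing: 2 kHz sampling (Nyquist well
    above the 300 Hz OP band edge), 350 ms epochs with 50 ms
    pre-stimulus baseline, a-trough at 15 ms, b-peak at 70 ms, four
    110 Hz OP wavelets starting at 15 ms.
    """

    a_amp: float = 150.0
    a_peak_ms: float = 15.0
    a_shape: float = 4.0
    b_amp_max: float = 600.0
    b_peak_ms: float = 70.0
    b_shape: float = 8.0
    nr_semisat: float = 1e-2       # linear cd*s/m^2
    nr_slope: float = 1.0
    op_gain: float = 0.15          # fraction of b-wave amplitude
    op_freq_hz: float = 110.0
    op_onset_ms: float = 15.0
    op_decay: float = 0.85         # per-wavelet amplitude ratio
    n_wavelets: int = 4
    pstr_amp: float = 25.0
    pstr_peak_ms: float = 110.0
    pstr_shape: float = 3.0
    noise_sd: float = 20.0         # per-sweep, microvolts
    fs_hz: float = 2000.0
    epoch_ms: float = 350.0
    pre_stim_ms: float = 50.0
    n_sweeps: int = 40
    threshold_log: float = -5.0    # no response below this intensity
    zones: ZoneBoundaries = field(default_factory=ZoneBoundaries)

    def __post_init__(self) -> None:
        numeric = {
            "a_amp": self.a_amp, "a_peak_ms": self.a_peak_ms,
            "a_shape": self.a_shape, "b_amp_max": self.b_amp_max,
            "b_peak_ms": self.b_peak_ms, "b_shape": self.b_shape,
            "nr_semisat": self.nr_semisat, "nr_slope": self.nr_slope,
            "op_gain": self.op_gain, "op_freq_hz": self.op_freq_hz,
            "op_onset_ms": self.op_onset_ms, "op_decay": self.op_decay,
            "pstr_amp": self.pstr_amp, "pstr_peak_ms": self.pstr_peak_ms,
            "pstr_shape": self.pstr_shape, "noise_sd": self.noise_sd,
            "fs_hz": self.fs_hz, "epoch_ms": self.epoch_ms,
            "pre_stim_ms": self.pre_stim_ms,
            "threshold_log": self.threshold_log,
        }
        for name, value in numeric.items():
            if not math.isfinite(float(value)):
                raise InvalidParamsError(f"{name} must be finite, got {value}")
        for name in ("a_amp", "b_amp_max", "op_gain", "pstr_amp", "noise_sd"):
            if numeric[name] < 0:
                raise InvalidParamsError(f"{name} must be >= 0")
        if self.nr_semisat <= 0 or self.nr_slope <= 0:
            raise InvalidParamsError("nr_semisat and nr_slope must be > 0")
        if not (65.0 < self.op_freq_hz < 300.0):
            raise InvalidParamsError("op_freq_hz must lie inside (65, 300) Hz")
        if self.n_wavelets < 1:
            raise InvalidParamsError("n_wavelets must be >= 1")
        if self.n_sweeps < 1:
            raise InvalidParamsError("n_sweeps must be >= 1")
        if self.fs_hz < 2.0 * 300.0:
            raise InvalidParamsError(
                "fs_hz must be >= 600 Hz so Nyquist covers the OP band"
            )
        if self.epoch_ms <= self.pre_stim_ms:
            raise InvalidParamsError("epoch_ms must exceed pre_stim_ms")

    def b_amplitude(self, intensity_log: float) -> float:
        """Ground-truth b-wave lobe amplitude at a given intensity."""
        if intensity_log < self.threshold_log:
            return 0.0
        return naka_rushton(
            10.0**intensity_log, self.b_amp_max, self.nr_semisat, self.nr_slope
        )

    def op_peak_times_ms(self) -> np.ndarray:
        """Ground-truth OP wavelet peak times (one carrier period apart)."""
        period = 1000.0 / self.op_freq_hz
        return self.op_onset_ms + period * np.arange(self.n_wavelets)

    def op_amplitudes(self, intensity_log: float) -> np.ndarray:
        """Ground-truth OP wavelet peak amplitudes at a given intensity."""
        b = self.b_amplitude(intensity_log)
        return self.op_gain * b * self.op_decay ** np.arange(self.n_wavelets)


def _gamma_lobe(t_ms: np.ndarray, peak_ms: float, shape: float) -> np.ndarray:
    """Smooth transient that is 0 for t<=0 and peaks at exactly 1 at peak_ms."""
    out = np.zeros_like(t_ms)
    pos = t_ms > 0
    x = t_ms[pos] / peak_ms
    out[pos] = x**shape * np.exp(shape * (1.0 - x))
    return out


def simulate_erg_epoch(
    params: ERGSimParams, intensity_log: float, seed: int
) -> ERGEpoch:
    """Synthesize one averaged scotopic ERG epoch.

    Deterministic for a fixed ``(params, intensity_log, seed)``. Below
    ``params.threshold_log`` there is no stimulus-driven response at
    all; with ``noise_sd = 0`` such an epoch is identically zero.
    """
    if not math.isfinite(float(intensity_log)):
        raise InvalidParamsError("intensity_log must be finite")
    t = make_time_grid(params.fs_hz, params.epoch_ms, params.pre_stim_ms)
    v = np.zeros_like(t)
    zone = classify_light_zone(intensity_log, params.zones)

    if intensity_log >= params.threshold_log:
        b_amp = params.b_amplitude(intensity_log)
        # b-wave: gamma-like positive transient
        v += b_amp * _gamma_lobe(t, params.b_peak_ms, params.b_shape)
        # a-wave: negative gamma-like lobe at photoreceptor-driving intensities
        if zone >= 3 and params.a_amp > 0:
            v -= params.a_amp * _gamma_lobe(t, params.a_peak_ms, params.a_shape)
        # OP wavelets: Gabor atoms, sigma of half a carrier period
        if params.op_gain > 0 and b_amp > 0:
            sigma = 0.5 * 1000.0 / params.op_freq_hz
            for k, (tk, ak) in enumerate(
                zip(params.op_peak_times_ms(), params.op_amplitudes(intensity_log))
            ):
                env = np.exp(-((t - tk) ** 2) / (2.0 * sigma**2))
                v += ak * env * np.cos(
                    2e-3 * np.pi * params.op_freq_hz * (t - tk)
                )
        # pSTR: slow positive lobe, the dominant response at rod threshold
        if zone == 1 and params.pstr_amp > 0:
            v += params.pstr_amp * _gamma_lobe(
                t, params.pstr_peak_ms, params.pstr_shape
            )
        v[t < 0] = 0.0  # all stimulus-driven energy after onset

    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(
            0.0, params.noise_sd / math.sqrt(params.n_sweeps), size=t.size
        )

    return ERGEpoch(
        time_ms=t,
        voltage_uv=v,
        intensity_log=float(intensity_log),
        fs_hz=params.fs_hz,
        meta={"zone": zone, "n_sweeps": params.n_sweeps, "seed": int(seed)},
    )


def simulate_intensity_series(
    params: ERGSimParams, intensities_log: Sequence[float], seed: int
) -> list[ERGEpoch]:
    """One epoch per intensity; element seeds split from the master seed."""
    if len(intensities_log) == 0:
        raise ValueError("intensities list is empty")
    return [
        simulate_erg_epoch(params, inten, split_seed(seed, i))
        for i, inten in enumerate(intensities_log)
    ]


# --------------------------------------------------------------------------
# Raw samples from printed summaries
# --------------------------------------------------------------------------

def make_group_samples(mean: float, sem: float, n: int, seed: int) -> np.ndarray:
    """A sample of size ``n`` whose mean and SEM match the targets exactly.

    Inverts the "mean +/- SEM" reporting convention: a seeded standard
    normal draw is affinely rescaled so the arithmetic mean equals
    ``mean`` and the sample SEM (sd with the n-1 denominator, divided
    by sqrt(n)) equals ``sem``, to floating-point accuracy.
    """
    n = int(n)
    if sem < 0:
        raise ValueError("sem must be >= 0")
    if n < 2:
        if sem > 0:
            raise ValueError("SEM is undefined for n < 2")
        return np.full(max(n, 1), float(mean))
    if sem == 0.0:
        return np.full(n, float(mean))
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    while np.std(x, ddof=1) == 0.0:  # zero-variance draw (measure zero)
        x = rng.standard_normal(n)
    z = (x - x.mean()) / np.std(x, ddof=1)
    target_sd = sem * math.sqrt(n)
    return float(mean) + z * target_sd


# --------------------------------------------------------------------------
# Oxygen-consumption traces
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class OCRSimParams:
    """Three-phase oxygen-consumption trace parameters.

    Phase levels in pmol O2/min: ``basal_level`` before any injection,
    ``fccp_plateau`` after the uncoupler FCCP, ``nonmito_level`` after
    rotenone/antimycin A. ``protein_mg`` is the punch protein content
    used for normalization.
    """

    basal_level: float = 120.0
    fccp_plateau: float = 150.0
    nonmito_level: float = 25.0
    n_basal: int = 4
    n_fccp: int = 4
    n_rotaa: int = 4
    interval_min: float = 6.5
    noise_sd: float = 0.0
    protein_mg: float = 0.01

    def __post_init__(self) -> None:
        for name in ("basal_level", "fccp_plateau", "nonmito_level"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise InvalidParamsError(f"{name} must be finite and >= 0")
        for name in ("n_basal", "n_fccp", "n_rotaa"):
            if getattr(self, name) < 1:
                raise InvalidParamsError(f"{name} must be >= 1")
        if self.noise_sd < 0:
            raise InvalidParamsError("noise_sd must be >= 0")
        if self.protein_mg <= 0:
            raise InvalidParamsError("protein_mg must be > 0")
        if self.interval_min <= 0:
            raise InvalidParamsError("interval_min must be > 0")


def simulate_ocr_trace(
    params: OCRSimParams, seed: int, well_id: str = "A1"
) -> pd.DataFrame:
    """Simulate a basal -> FCCP -> rotenone/antimycin-A OCR trace.

    Returns a tidy table with columns ``well_id, time_min,
    ocr_pmol_min, phase``; with ``noise_sd = 0`` the phase means equal
    the configured levels exactly.
    """
    rng = np.random.default_rng(seed)
    levels = (
        [params.basal_level] * params.n_basal
        + [params.fccp_plateau] * params.n_fccp
        + [params.nonmito_level] * params.n_rotaa
    )
    phases = (
        ["basal"] * params.n_basal
        + ["fccp"] * params.n_fccp
        + ["rotaa"] * params.n_rotaa
    )
    n = len(levels)
    ocr = np.asarray(levels, dtype=float)
    if params.noise_sd > 0:
        ocr = ocr + rng.normal(0.0, params.noise_sd, size=n)
    return pd.DataFrame(
        {
            "well_id": well_id,
            "time_min": (np.arange(n) + 1) * params.interval_min,
            "ocr_pmol_min": ocr,
            "phase": phases,
        }
    )


# --------------------------------------------------------------------------
# Longitudinal cohorts from printed group summaries
# --------------------------------------------------------------------------

#: fasting blood glucose cut-off (mmol/L) for diabetic inclusion, inclusive
GLUCOSE_INCLUSION_MMOL_L: float = 13.9


@dataclass(frozen=True)
class CohortDesign:
    """Design of a longitudinal two-group cohort.

    ``targets[variable][group][week] = (mean, sem)`` must be complete
    over ``groups`` x ``weeks`` for every variable.
    """

    group_sizes: Mapping[str, int]
    weeks: Sequence[int]
    targets: Mapping[str, Mapping[str, Mapping[int, tuple[float, float]]]]

    def validate(self) -> None:
        if not self.group_sizes or not len(self.weeks) or not self.targets:
            raise ValueError("cohort design is incomplete")
        for var, per_group in self.targets.items():
            for group in self.group_sizes:
                if group not in per_group:
                    raise ValueError(f"design missing group {group!r} for {var!r}")
                for week in self.weeks:
                    if week not in per_group[group]:
                        raise ValueError(
                            f"design missing week {week} for {var!r}/{group!r}"
                        )


def simulate_cohort(design: CohortDesign, seed: int) -> pd.DataFrame:
    """Long-format cohort table (animal, group, week, variable, value).

    Each (variable, group, week) cell is a :func:`make_group_samples`
    draw hitting the designed mean and SEM exactly; animal identity is
    consistent across weeks and variables.
    """
    design.validate()
    rows = []
    cell_index = 0
    for var in design.targets:
        for group, size in design.group_sizes.items():
            for week in design.weeks:
                mean, sem = design.targets[var][group][week]
                values = make_group_samples(
                    mean, sem, size, split_seed(seed, cell_index)
                )
                cell_index += 1
                for j, val in enumerate(values):
                    rows.append(
                        {
                            "animal": f"{group}-{j + 1}",
                            "group": group,
                            "week": int(week),
                            "variable": var,
                            "value": float(val),
                        }
                    )
    return pd.DataFrame(rows)


def inclusion_flags(
    cohort: pd.DataFrame,
    threshold: float = GLUCOSE_INCLUSION_MMOL_L,
    week: int = 9,
    variable: str = "glucose",
) -> pd.Series:
    """Diabetic-inclusion flag per animal: week-9 fasting glucose >= threshold.

    The bound is inclusive: a value of exactly 13.9 mmol/L is included.
    Returns a boolean Series indexed by animal id.
    """
    sel = cohort[(cohort["week"] == week) & (cohort["variable"] == variable)]
    if sel.empty:
        raise ValueError(f"no {variable!r} values at week {week}")
    return sel.set_index("animal")["value"] >= threshold
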