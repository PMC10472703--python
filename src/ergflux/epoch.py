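"""The ERG epoch container: one averaged scotopic sweep on a uniform grid."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

#: relative tolerance for uniform-grid validation
_GRID_RTOL = 1e-9


class InvalidEpochError(ValueError):
    """Raised when an epoch violates its structural invariants."""


@dataclass
class ERGEpoch:
    """One averaged scotopic ERG sweep.

    Attributes
    ----------
    time_ms
        Uniformly spaced sample times in ms; 0 marks stimulus onset and
        negative times are the pre-stimulus baseline.
    voltage_uv
        Corneal potential in microvolts, one value per sample.
    intensity_log
        Flash strength in log cd*s/m^2 (scotopic units).
    fs_hz
        Sampling rate in Hz; must agree with the time grid.
    meta
        Free-form labels (animal id, group, age_weeks, sweep count...).
    """

    time_ms: np.ndarray
    voltage_uv: np.ndarray
    intensity_log: float
    fs_hz: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.voltage_uv = np.asarray(self.voltage_uv, dtype=float)
        if self.time_ms.ndim != 1 or self.voltage_uv.ndim != 1:
            raise InvalidEpochError("time and voltage must be 1-D vectors")
        if self.time_ms.size != self.voltage_uv.size:
            raise InvalidEpochError(
                f"time ({self.time_ms.size}) and voltage "
                f"({self.voltage_uv.size}) lengths differ"
            )
        if self.time_ms.size < 2:
            raise InvalidEpochError("epoch needs at least 2 samples")
        if not np.all(np.isfinite(self.voltage_uv)):
            raise InvalidEpochError("voltage contains non-finite values")
        if not np.all(np.isfinite(self.time_ms)):
            raise InvalidEpochError("time contains non-finite values")
        if not np.isfinite(self.intensity_log):
            raise InvalidEpochError("intensity_log must be finite")
        steps = np.diff(self.time_ms)
        if np.any(steps <= 0):
            raise InvalidEpochError("time must be strictly increasing")
        nominal = 1000.0 / self.fs_hz
        if np.any(np.abs(steps - nominal) > _GRID_RTOL * max(nominal, 1.0)):
            raise InvalidEpochError(
                f"time grid not uniform at 1000/fs = {nominal} ms"
            )

    @property
    def n_samples(self) -> int:
        return int(self.time_ms.size)

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.fs_hz

    @property
    def pre_stim(self) -> np.ndarray:
        """Boolean mask of pre-stimulus (t < 0) samples."""
        return self.time_ms < 0.0

    def with_voltage(self, voltage_uv: np.ndarray, **meta: Any) -> "ERGEpoch":
        """Copy of this epoch with a new voltage trace (same grid)."""
        out = replace(self, voltage_uv=np.asarray(voltage_uv, dtype=float))
        out.meta = {**self.meta, **meta}
        return out


def make_time_grid(fs_hz: float, epoch_ms: float, pre_stim_ms: float) -> np.ndarray:
    """Uniform time base in ms from -pre_stim_ms to epoch_ms - pre_stim_ms."""
    if epoch_ms <= pre_stim_ms:
        raise ValueError("epoch_ms must exceed pre_stim_ms")
    dt = 1000.0 / fs_hz
    n = int(round(epoch_ms / dt))
    return np.arange(n) * dt - pre_stim_ms
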