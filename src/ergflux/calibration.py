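"""Stimulus calibration: log cd*s/m^2 to photoisomerizations per rod,
light-zone classification, and the rod operating-range mask.

Scotopic stimulus strengths are calibrated with the standard conversion
1 scot cd/m^2 = 516 R*/rod/s, so a flash of energy E (in scot cd*s/m^2)
delivers 516*E photoisomerizations per rod. Stimuli are binned into the
four light zones of the murine scotopic ERG (rod threshold, rod-bipolar,
mixed rod/cone-bipolar, cone-involved); only the boundary between the
mixed and cone zones (-0.3 log cd*s/m^2, the upper end of the rod
operating range) is fixed by the protocol, the others are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

#: photoisomerizations per rod per second for 1 scotopic cd/m^2
R_STAR_PER_SCOT_CD: float = 516.0

#: upper bound (exclusive) of the rod operating range, log cd*s/m^2
ROD_RANGE_MAX_LOG: float = -0.3


@dataclass(frozen=True)
class ZoneBoundaries:
    """Upper bounds (inclusive) of light zones 1-3 in log cd*s/m^2.

    Zone 4 is everything above ``zone3_max``. The zone-3/4 split is the
    rod operating-range bound; the two dimmer splits separate the
    rod-threshold and rod-bipolar regimes and are convention choices.
    """

    zone1_max: float = -3.8
    zone2_max: float = -2.0
    zone3_max: float = ROD_RANGE_MAX_LOG

    def __post_init__(self) -> None:
        if not self.zone1_max < self.zone2_max < self.zone3_max:
            raise ValueError("zone boundaries must be strictly increasing")


DEFAULT_ZONES = ZoneBoundaries()


@dataclass(frozen=True)
class StimulusSpec:
    """A calibrated stimulus: log intensity, R*/rod, and light zone."""

    intensity_log: float
    r_star: float
    zone: int

    @classmethod
    def from_log_intensity(
        cls, intensity_log: float, zones: ZoneBoundaries = DEFAULT_ZONES
    ) -> "StimulusSpec":
        return cls(
            intensity_log=float(intensity_log),
            r_star=log_intensity_to_isomerizations(intensity_log),
            zone=classify_light_zone(intensity_log, zones),
        )


def log_intensity_to_isomerizations(intensity_log: float) -> float:
    """Convert flash energy in log cd*s/m^2 to photoisomerizations/rod.

    Returns ``10**intensity_log * 516``: the flash energy in linear
    scotopic cd*s/m^2 times the rod photoisomerization rate constant.
    """
    intensity_log = float(intensity_log)
    if not np.isfinite(intensity_log):
        raise ValueError("intensity_log must be finite")
    return 10.0**intensity_log * R_STAR_PER_SCOT_CD


def classify_light_zone(
    intensity_log: float, zones: ZoneBoundaries = DEFAULT_ZONES
) -> int:
    """Assign a stimulus to light zone 1, 2, 3 or 4 (monotone in intensity)."""
    intensity_log = float(intensity_log)
    if not np.isfinite(intensity_log):
        raise ValueError("intensity_log must be finite")
    if intensity_log <= zones.zone1_max:
        return 1
    if intensity_log <= zones.zone2_max:
        return 2
    if intensity_log <= zones.zone3_max:
        return 3
    return 4


def rod_range_mask(
    intensities_log: Sequence[float] | Iterable[float],
    max_log: float = ROD_RANGE_MAX_LOG,
) -> np.ndarray:
    """True where a stimulus lies in the rod operating range.

    The bound is strict: a flash is rod-range iff its intensity is
    *less than* ``max_log`` (default -0.3 log cd*s/m^2).
    """
    arr = np.asarray(list(intensities_log) if not isinstance(
        intensities_log, np.ndarray) else intensities_log, dtype=float)
    if arr.size == 0:
        raise ValueError("intensity list is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError("intensities must be finite")
    return arr < max_log
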