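"""Naka-Rushton intensity-response fitting for the scotopic b-wave.

The b-wave amplitude V as a function of linear flash intensity I follows
the saturating hyperbolic function

    V(I) = Bmax * I^n / (I^n + sigma^n)

which is sigmoidal on a log-intensity axis. ``Bmax`` is the asymptotic
maximum b-wave response, ``sigma`` the semisaturation intensity
(V(sigma) = Bmax/2) and ``n`` a Hill-type slope. Fits are restricted to
stimuli within the rod operating range (< -0.3 log cd*s/m^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from ergflux.calibration import ROD_RANGE_MAX_LOG, rod_range_mask


class FitError(RuntimeError):
    """Raised when an intensity-response fit cannot be performed."""


@dataclass(frozen=True)
class IntensityResponseFit:
    """Fitted Naka-Rushton parameters with diagnostics.

    ``bmax`` in microvolts, ``semisat`` in linear cd*s/m^2, ``slope_n``
    dimensionless, ``rss`` the residual sum of squares in uV^2.
    """

    bmax: float
    semisat: float
    slope_n: float
    rss: float
    n_points: int
    converged: bool

    def predict(self, intensity_linear: np.ndarray | float) -> np.ndarray | float:
        return naka_rushton(intensity_linear, self.bmax, self.semisat, self.slope_n)


def naka_rushton(
    intensity_linear: np.ndarray | float,
    bmax: float,
    semisat: float,
    slope_n: float,
) -> np.ndarray | float:
    """Saturating hyperbolic response bmax * I^n / (I^n + semisat^n)."""
    if bmax < 0 or semisat <= 0 or slope_n <= 0:
        raise ValueError("require bmax >= 0, semisat > 0, slope_n > 0")
    arr = np.asarray(intensity_linear, dtype=float)
    if np.any(arr < 0):
        raise ValueError("intensity must be non-negative (linear units)")
    i_n = arr**slope_n
    out = bmax * i_n / (i_n + semisat**slope_n)
    if np.ndim(intensity_linear) == 0:
        return float(out)
    return out


def fit_naka_rushton(
    intensities_log: np.ndarray,
    amplitudes: np.ndarray,
    fix_n: float | None = None,
    apply_rod_mask: bool = True,
    rod_max_log: float = ROD_RANGE_MAX_LOG,
    n_starts: int = 5,
) -> IntensityResponseFit:
    """Least-squares Naka-Rushton fit of b-wave amplitude vs intensity.

    Intensities are supplied in log cd*s/m^2 and converted to the
    hyperbola's natural linear variable. By default only rod-range
    points (< ``rod_max_log``) enter the fit. The residual sum of
    squares is minimized over (bmax, semisat, slope_n) with bounds
    bmax in [0, 2*max(amplitude)], semisat within the data range
    widened by one log unit, slope_n in [0.5, 3]; a deterministic grid
    of ``n_starts`` semisaturation starts makes the multi-start
    reproducible without a seed. ``fix_n`` pins the slope (e.g. at 1
    for the exponent-free hyperbola).
    """
    intensities_log = np.asarray(intensities_log, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if intensities_log.shape != amplitudes.shape:
        raise ValueError("intensities and amplitudes must have equal shape")
    if np.any(amplitudes < 0):
        raise ValueError("amplitudes must be >= 0")
    if apply_rod_mask:
        mask = rod_range_mask(intensities_log, rod_max_log)
        intensities_log = intensities_log[mask]
        amplitudes = amplitudes[mask]
    if intensities_log.size < 3:
        raise FitError(
            f"need >= 3 rod-range points, got {intensities_log.size}"
        )
    if np.all(amplitudes == 0):
        raise FitError("all amplitudes are zero; response is degenerate")

    intensity = 10.0**intensities_log
    amp_max = float(amplitudes.max())
    lo_log = float(intensities_log.min()) - 1.0
    hi_log = float(intensities_log.max()) + 1.0

    def residuals(theta: np.ndarray) -> np.ndarray:
        bmax, log_sigma = theta[0], theta[1]
        n = theta[2] if fix_n is None else fix_n
        return naka_rushton(intensity, bmax, 10.0**log_sigma, n) - amplitudes

    if fix_n is None:
        lower = [0.0, lo_log, 0.5]
        upper = [2.0 * amp_max, hi_log, 3.0]
    else:
        if not (fix_n > 0):
            raise ValueError("fix_n must be > 0")
        lower = [0.0, lo_log]
        upper = [2.0 * amp_max, hi_log]

    sigma_starts = np.linspace(lo_log + 0.25, hi_log - 0.25, n_starts)
    best = None
    for s in sigma_starts:
        x0 = [amp_max, s] if fix_n is not None else [amp_max, s, 1.0]
        try:
            sol = least_squares(
                residuals, x0=x0, bounds=(lower, upper),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:  # a start failing must not kill the multi-start
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol)
    if best is None:
        return IntensityResponseFit(
            bmax=math.nan, semisat=math.nan, slope_n=math.nan,
            rss=math.inf, n_points=intensities_log.size, converged=False,
        )
    rss, sol = best
    bmax = float(sol.x[0])
    semisat = float(10.0 ** sol.x[1])
    slope_n = float(fix_n if fix_n is not None else sol.x[2])
    return IntensityResponseFit(
        bmax=bmax, semisat=semisat, slope_n=slope_n, rss=rss,
        n_points=int(intensities_log.size), converged=bool(sol.success),
    )


def bmax_of(fit: IntensityResponseFit) -> float:
    """The asymptotic maximum b-wave response of a converged fit."""
    if not fit.converged:
        raise FitError("fit did not converge; Bmax is undefined")
    return fit.bmax
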