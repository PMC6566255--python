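"""Single-scale to whole-wing spectrum conversion.

A wing is a loose pile of scale layers: melanin-bearing ground scales add a
smooth, nearly linear reflectance background, and the random angular
distribution of the scales smears the single-scale spectrum.  Both effects
are modeled here: a linear background line added to the spectrum and a
Gaussian broadening of configurable width.  Vapor measurements are read out
as relative spectra, the pointwise ratio of the vapor-on and vapor-off
whole-wing spectra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .optics import RelativeSpectrum, Spectrum

__all__ = [
    "BackgroundLine",
    "fit_background",
    "whole_wing_spectrum",
    "relative_spectrum",
    "DEFAULT_LOW_WINDOW",
    "DEFAULT_HIGH_WINDOW",
    "DEFAULT_SIGMA_NM",
    "DEFAULT_FLOOR",
]

DEFAULT_LOW_WINDOW = (200.0, 250.0)
DEFAULT_HIGH_WINDOW = (750.0, 800.0)
DEFAULT_SIGMA_NM = 15.0
DEFAULT_FLOOR = 1e-4


@dataclass(frozen=True)
class BackgroundLine:
    """Linear melanin/ground-scale background, reflectance = intercept + slope*lambda."""

    intercept: float
    slope: float

    def __call__(self, wavelengths: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(wavelengths, dtype=float)


def fit_background(
    reference: Spectrum,
    low_window: tuple[float, float] = DEFAULT_LOW_WINDOW,
    high_window: tuple[float, float] = DEFAULT_HIGH_WINDOW,
) -> BackgroundLine:
    """Least-squares line through the short- and long-wavelength flanks.

    The two windows must avoid the structural peak; together they pin the
    smooth background underneath it.
    """
    lo0, lo1 = low_window
    hi0, hi1 = high_window
    if lo1 > hi0:
        raise ValueError("background windows must not overlap")
    wl, v = reference.wavelengths, reference.values
    mask = ((wl >= lo0) & (wl <= lo1)) | ((wl >= hi0) & (wl <= hi1))
    if mask.sum() < 2:
        raise ValueError("background windows contain fewer than 2 grid points")
    slope, intercept = np.polyfit(wl[mask], v[mask], 1)
    return BackgroundLine(intercept=float(intercept), slope=float(slope))


def whole_wing_spectrum(
    scale_spectrum: Spectrum,
    bg: BackgroundLine,
    sigma: float = DEFAULT_SIGMA_NM,
) -> Spectrum:
    """Gaussian-broadened scale spectrum plus the background line.

    ``sigma`` is the broadening width in nm (scale-orientation spread);
    the kernel is normalized on the grid and edges use nearest-value
    padding, so a constant spectrum stays constant.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    wl = scale_spectrum.wavelengths
    if sigma == 0:
        broadened = scale_spectrum.values.copy()
    else:
        step = float(wl[1] - wl[0]) if wl.size > 1 else 1.0
        if wl.size > 2 and not np.allclose(np.diff(wl), step):
            raise ValueError("Gaussian broadening requires a uniform grid")
        broadened = gaussian_filter1d(scale_spectrum.values, sigma / step, mode="nearest")
    return Spectrum(wl, broadened + bg(wl))


def relative_spectrum(
    R_vapor: Spectrum,
    R_zero: Spectrum,
    floor: float = DEFAULT_FLOOR,
) -> RelativeSpectrum:
    """Pointwise ratio vapor-on / vapor-off, denominator clamped at ``floor``.

    The clamp guards the deep-UV region where chitin absorption can push
    the reference reflectance toward zero.
    """
    if not R_vapor.same_grid(R_zero):
        raise ValueError("spectra must share one wavelength grid")
    denom = np.maximum(R_zero.values, floor)
    num = np.maximum(R_vapor.values, floor)
    return RelativeSpectrum(R_vapor.wavelengths, num / denom)
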