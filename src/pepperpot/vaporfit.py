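"""Least-squares recovery of the condensation/swelling parameters.

Measured relative reflectance spectra at a vapor concentration ``x`` are
fitted with the forward model by minimizing the integral of the squared
residual over a wavelength window,

    Delta = integral_{lmin}^{lmax} [ rho_measured - rho_model ]^2 dlambda.

At fixed swelling ``s`` the model relative spectrum is affine in the two
filling weights (the broadening and background are affine maps and the
zero-vapor denominator carries no parameters), so the inner problem is a
bounded linear least squares; the swelling enters nonlinearly through the
spectral rescale and is handled by a deterministic grid search with
golden-section refinement.  The fit is done at the largest concentration
and extrapolated downward with the linear-in-x law.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import lsq_linear, minimize_scalar

from .optics import FillingState, RelativeSpectrum, Spectrum

__all__ = [
    "FitCoefficients",
    "NonIdentifiableModelError",
    "residual_integral",
    "fit_state",
    "linearize_in_x",
    "filling_factors",
    "peak_shift",
    "peak_wavelength",
    "DEFAULT_PEAK_WINDOW",
    "DORSAL_ETHANOL_LAW",
    "VENTRAL_ETHANOL_LAW",
]

DEFAULT_PEAK_WINDOW = (400.0, 700.0)


class NonIdentifiableModelError(RuntimeError):
    """The forward model does not separate the filling processes."""


@dataclass(frozen=True)
class FitCoefficients:
    """Linear-in-concentration law: c_B = cB_slope*x, c_AB = cAB_slope*x, s = s_slope*x."""

    cB_slope: float
    cAB_slope: float
    s_slope: float
    residual: float = 0.0

    def state_at(self, x: float) -> FillingState:
        return FillingState(x=x, c_B=self.cB_slope * x, c_AB=self.cAB_slope * x,
                            s=self.s_slope * x)


# Fitted ethanol-response laws of the two wing sides: c_B, c_AB and s as
# linear functions of the vapor concentration x.  At x = 0.5 the dorsal law
# gives (c_B, c_AB, s) = (0.04, 0.04, 0.008), i.e. f_B = 8%, f_A = 4% and
# 0.8% swelling; the ventral law gives (0.2, 0, 0.006): f_B = 20%, f_A = 0%.
DORSAL_ETHANOL_LAW = FitCoefficients(cB_slope=0.08, cAB_slope=0.08, s_slope=0.016)
VENTRAL_ETHANOL_LAW = FitCoefficients(cB_slope=0.4, cAB_slope=0.0, s_slope=0.012)


def residual_integral(
    measured: Spectrum,
    modeled: Spectrum,
    lambda_min: float = 200.0,
    lambda_max: float = 800.0,
) -> float:
    """Trapezoidal integral of the squared difference over the window."""
    if not measured.same_grid(modeled):
        raise ValueError("measured and modeled spectra must share one grid")
    wl = measured.wavelengths
    if lambda_min < wl[0] - 1e-9 or lambda_max > wl[-1] + 1e-9:
        raise ValueError("integration window outside the wavelength grid")
    mask = (wl >= lambda_min) & (wl <= lambda_max)
    diff = measured.values[mask] - modeled.values[mask]
    return float(np.trapezoid(diff**2, wl[mask]))


def _solve_cs(
    forward: Callable[[FillingState], RelativeSpectrum],
    measured: RelativeSpectrum,
    x: float,
    s: float,
    bounds: tuple[float, float],
    window: tuple[float, float],
) -> tuple[float, float, float]:
    """Inner bounded linear least squares in (c_B, c_AB) at fixed s."""
    base = forward(FillingState(x=x, c_B=0.0, c_AB=0.0, s=s))
    col_b = forward(FillingState(x=x, c_B=1.0, c_AB=0.0, s=s)).values - base.values
    col_ab = forward(FillingState(x=x, c_B=0.0, c_AB=1.0, s=s)).values - base.values
    if np.linalg.norm(col_b) < 1e-12 and np.linalg.norm(col_ab) < 1e-12:
        raise NonIdentifiableModelError(
            "filling scenarios produce identical spectra; c_B and c_AB are not identifiable"
        )
    wl = measured.wavelengths
    mask = (wl >= window[0]) & (wl <= window[1])
    # trapezoid quadrature weights make the discrete problem match Delta
    w = np.gradient(wl[mask])
    w[0] /= 2.0
    w[-1] /= 2.0
    sw = np.sqrt(w)
    A = np.column_stack([col_b[mask] * sw, col_ab[mask] * sw])
    y = (measured.values[mask] - base.values[mask]) * sw
    res = lsq_linear(A, y, bounds=(bounds[0], bounds[1]), method="bvls")
    c_b, c_ab = float(res.x[0]), float(res.x[1])
    if c_b + c_ab > 1.0:  # rare: project back onto the simplex edge
        excess = (c_b + c_ab - 1.0) / 2.0
        c_b, c_ab = max(c_b - excess, 0.0), max(c_ab - excess, 0.0)
    modeled = forward(FillingState(x=x, c_B=c_b, c_AB=c_ab, s=s))
    delta = residual_integral(measured, modeled, window[0], window[1])
    return c_b, c_ab, delta


def fit_state(
    measured: RelativeSpectrum,
    forward: Callable[[FillingState], RelativeSpectrum],
    x_fit: float = 0.5,
    c_bounds: tuple[float, float] = (0.0, 1.0),
    s_bounds: tuple[float, float] = (0.0, 0.05),
    s_grid_points: int = 26,
    window: tuple[float, float] = (200.0, 800.0),
) -> FillingState:
    """Arg-min of the residual integral over (c_B, c_AB, s).

    Outer deterministic search over the swelling: a uniform grid of
    ``s_grid_points`` values followed by bounded golden-section refinement
    between the neighbors of the best grid point; inner bounded linear
    least squares in the filling weights.
    """
    s_values = np.linspace(s_bounds[0], s_bounds[1], s_grid_points)

    def objective(s: float) -> float:
        return _solve_cs(forward, measured, x_fit, float(s), c_bounds, window)[2]

    deltas = np.array([objective(s) for s in s_values])
    i = int(np.argmin(deltas))
    lo = s_values[max(i - 1, 0)]
    hi = s_values[min(i + 1, len(s_values) - 1)]
    if hi > lo:
        res = minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-9})
        s_best = float(res.x)
        if res.fun > deltas[i]:
            s_best = float(s_values[i])
    else:
        s_best = float(s_values[i])
    c_b, c_ab, _ = _solve_cs(forward, measured, x_fit, s_best, c_bounds, window)
    return FillingState(x=x_fit, c_B=c_b, c_AB=c_ab, s=s_best)


def linearize_in_x(state_at_xfit: FillingState, x_fit: float,
                   residual: float = 0.0) -> FitCoefficients:
    """Linear-in-x law from the single fit at concentration ``x_fit``."""
    if x_fit <= 0:
        raise ValueError("x_fit must be positive")
    return FitCoefficients(
        cB_slope=state_at_xfit.c_B / x_fit,
        cAB_slope=state_at_xfit.c_AB / x_fit,
        s_slope=state_at_xfit.s / x_fit,
        residual=residual,
    )


def filling_factors(state: FillingState) -> tuple[float, float]:
    """Layer filling factors ``(f_A, f_B) = (c_AB, c_AB + c_B)``."""
    return state.f_A, state.f_B


def peak_wavelength(
    spectrum: Spectrum,
    search_window: tuple[float, float] = DEFAULT_PEAK_WINDOW,
) -> float:
    """Main-peak wavelength with sub-grid precision.

    Locates the grid maximum inside the window and refines it with a
    parabola through the maximum and its two neighbors; a maximum on the
    window edge is flagged as an error.
    """
    wl, v = spectrum.wavelengths, spectrum.values
    mask = (wl >= search_window[0]) & (wl <= search_window[1])
    idx = np.flatnonzero(mask)
    if idx.size < 3:
        raise ValueError("search window contains fewer than 3 grid points")
    k = idx[np.argmax(v[idx])]
    if k == idx[0] or k == idx[-1]:
        raise ValueError(
            f"maximum at the window edge ({wl[k]:.1f} nm); widen the search window"
        )
    y0, y1, y2 = v[k - 1], v[k], v[k + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(wl[k])
    offset = 0.5 * (y0 - y2) / denom
    step = wl[k + 1] - wl[k]
    return float(wl[k] + offset * step)


def peak_shift(
    R_vapor: Spectrum,
    R_zero: Spectrum,
    search_window: tuple[float, float] = DEFAULT_PEAK_WINDOW,
) -> float:
    """Shift of the main peak (vapor-on minus vapor-off), in nm."""
    return peak_wavelength(R_vapor, search_window) - peak_wavelength(R_zero, search_window)
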