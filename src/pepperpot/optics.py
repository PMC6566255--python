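"""Normal-incidence reflectance of the effective multilayer and the
condensation/swelling mixing model.

The 1D+2D nanoarchitecture is reduced layer-by-layer to homogeneous
effective media (see :mod:`pepperpot.geometry`) and solved with the
standard characteristic-matrix (transfer-matrix) recursion at normal
incidence.  Partial liquid filling of the air network enters through
incoherent mixing: regions whose voids are filled lie farther apart than
the coherence length of white light, so their reflectances (not fields)
add,

    R(lambda) = (1 - cB - cAB) R0(lambda') + cB RB(lambda') + cAB RAB(lambda'),

with lambda' = lambda / (1 + s) implementing an isotropic swelling of the
chitin skeleton by the fraction ``s`` (a red shift of every component).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import OpticalMedia, ScaleGeometry, effective_stack

__all__ = [
    "Spectrum",
    "RelativeSpectrum",
    "FillingState",
    "default_grid",
    "multilayer_rt",
    "multilayer_reflectance",
    "scenario_stack",
    "mix_spectra",
]


def default_grid() -> np.ndarray:
    """The standard 200-800 nm wavelength grid in 2 nm steps (301 points)."""
    return np.arange(200.0, 800.0 + 1.0, 2.0)


@dataclass(frozen=True)
class Spectrum:
    """Reflectance sampled on a strictly increasing wavelength grid (nm)."""

    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", v)
        if wl.ndim != 1 or v.shape != wl.shape:
            raise ValueError("wavelengths and values must be 1D arrays of equal length")
        if wl.size >= 2 and not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("spectrum values must be finite")

    def same_grid(self, other: "Spectrum") -> bool:
        return self.wavelengths.shape == other.wavelengths.shape and np.allclose(
            self.wavelengths, other.wavelengths, rtol=0, atol=1e-9
        )

    def at(self, wavelengths: np.ndarray) -> np.ndarray:
        """Linear interpolation, clamped to the boundary values outside the grid."""
        return np.interp(wavelengths, self.wavelengths, self.values)


class RelativeSpectrum(Spectrum):
    """Ratio of a vapor-on to the vapor-off reflectance spectrum (~1)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.any(self.values <= 0):
            raise ValueError("relative reflectance must be positive")


@dataclass(frozen=True)
class FillingState:
    """Condensation/swelling state at one vapor concentration.

    ``c_B`` weights the process filling only the B-layer channels, ``c_AB``
    the process filling both layers; ``s`` is the fractional isotropic
    swelling.  The layer filling factors follow as ``f_A = c_AB`` and
    ``f_B = c_AB + c_B``.
    """

    x: float
    c_B: float
    c_AB: float
    s: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.x <= 1.0:
            raise ValueError("vapor concentration x must be in [0, 1]")
        if self.c_B < 0 or self.c_AB < 0:
            raise ValueError("filling weights must be non-negative")
        if self.c_B + self.c_AB > 1.0 + 1e-12:
            raise ValueError("c_B + c_AB must not exceed 1")
        if self.s < 0:
            raise ValueError("swelling s must be non-negative")

    @property
    def f_A(self) -> float:
        return self.c_AB

    @property
    def f_B(self) -> float:
        return self.c_AB + self.c_B


def multilayer_rt(
    stack: list[tuple[complex, float]],
    n_ambient: complex,
    n_substrate: complex,
    grid: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Reflectance and transmittance of a planar stack at normal incidence.

    ``stack`` lists layers from the side the light enters, as
    ``(complex index, thickness nm)``.  The characteristic matrix of each
    layer is accumulated and the stack amplitude coefficients follow from
    the ambient/substrate admittances.  An empty stack reduces to the bare
    Fresnel interface.
    """
    grid = np.asarray(grid, dtype=float)
    for j, (n, d) in enumerate(stack):
        if d <= 0:
            raise ValueError(f"layer {j}: thickness must be positive, got {d}")
        n = complex(n)
        if n.real < 1 or n.imag < 0:
            raise ValueError(f"layer {j}: index {n} must have Re >= 1, Im >= 0")

    # The characteristic-matrix recursion is written in the n - ik convention
    # (Macleod); this package states absorbing indices as n + ik, so all
    # indices are conjugated here.  R and T are convention-free.
    n0 = np.conj(complex(n_ambient))
    ns = np.conj(complex(n_substrate))
    # (B, C) = M_1 ... M_N @ (1, ns), layer 1 adjacent to the ambient, so the
    # matrices are applied substrate-side first; admittance = index at normal
    # incidence.
    B = np.ones_like(grid, dtype=complex)
    C = np.full_like(grid, ns, dtype=complex)
    for n, d in reversed(stack):
        n = np.conj(complex(n))
        delta = 2.0 * np.pi * n * d / grid
        cosd = np.cos(delta)
        sind = np.sin(delta)
        B_new = cosd * B + 1j * sind / n * C
        C_new = 1j * n * sind * B + cosd * C
        B, C = B_new, C_new
    r = (n0 * B - C) / (n0 * B + C)
    t = 2.0 * n0 / (n0 * B + C)
    R = np.abs(r) ** 2
    T = (ns.real / n0.real) * np.abs(t) ** 2
    return R, T


def multilayer_reflectance(
    stack: list[tuple[complex, float]],
    n_ambient: complex = 1.0,
    n_substrate: complex = 1.0,
    grid: np.ndarray | None = None,
) -> Spectrum:
    """Reflectance spectrum ``|r|^2`` of a planar stack at normal incidence."""
    if grid is None:
        grid = default_grid()
    R, _ = multilayer_rt(stack, n_ambient, n_substrate, grid)
    if np.any(R > 1.0 + 1e-9):
        raise AssertionError("reflectance exceeded 1; non-physical stack")
    return Spectrum(np.asarray(grid, dtype=float), np.clip(R, 0.0, 1.0))


_SCENARIOS = ("air", "B_filled", "AB_filled")


def scenario_stack(
    geom: ScaleGeometry,
    media: OpticalMedia,
    scenario: str,
) -> list[tuple[complex, float]]:
    """Effective layer stack for one filling scenario.

    Light impinges on the top B layer, so the stack is ``n_stories``
    repetitions of (B, A) from the top.  ``scenario`` selects the void
    medium per layer: ``air`` (all air), ``B_filled`` (ethanol in the B
    channels only) or ``AB_filled`` (ethanol everywhere).
    """
    if scenario not in _SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {_SCENARIOS}")
    fill_a = media.n_ethanol if scenario == "AB_filled" else media.n_air
    fill_b = media.n_ethanol if scenario in ("B_filled", "AB_filled") else media.n_air
    eff = effective_stack(geom, media, void_medium_a=fill_a, void_medium_b=fill_b)
    layers: list[tuple[complex, float]] = []
    for _ in range(geom.n_stories):
        layers.append((eff.n_b, geom.d_b))
        layers.append((eff.n_a, geom.d_a))
    return layers


def scenario_reflectances(
    geom: ScaleGeometry,
    media: OpticalMedia,
    grid: np.ndarray | None = None,
) -> tuple[Spectrum, Spectrum, Spectrum]:
    """(R0, RB, RAB): all-air, B-filled and AB-filled single-scale spectra."""
    if grid is None:
        grid = default_grid()
    return tuple(
        multilayer_reflectance(scenario_stack(geom, media, sc), media.n_air, media.n_air, grid)
        for sc in _SCENARIOS
    )


def mix_spectra(R0: Spectrum, RB: Spectrum, RAB: Spectrum, state: FillingState) -> Spectrum:
    """Incoherent filling mixture with isotropic swelling.

    Each component is evaluated at ``lambda / (1 + s)`` (linear
    interpolation, boundary-clamped), so a positive swelling red-shifts the
    spectrum; the weights ``(1 - cB - cAB, cB, cAB)`` sum to one.
    """
    if not (R0.same_grid(RB) and R0.same_grid(RAB)):
        raise ValueError("component spectra must share one wavelength grid")
    lam = R0.wavelengths
    lam_src = lam / (1.0 + state.s)
    w0 = 1.0 - state.c_B - state.c_AB
    mixed = w0 * R0.at(lam_src) + state.c_B * RB.at(lam_src) + state.c_AB * RAB.at(lam_src)
    return Spectrum(lam, mixed)
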