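"""Forward model chain: geometry -> scenario reflectances -> whole wing ->
relative spectra as a function of the condensation/swelling state."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import OpticalMedia, ScaleGeometry
from .optics import (
    FillingState,
    RelativeSpectrum,
    Spectrum,
    default_grid,
    mix_spectra,
    scenario_reflectances,
)
from .wholewing import (
    DEFAULT_FLOOR,
    DEFAULT_SIGMA_NM,
    BackgroundLine,
    relative_spectrum,
    whole_wing_spectrum,
)

__all__ = ["VaporResponseModel", "DEFAULT_BACKGROUND"]

# Modest melanin background rising toward the red; reflectance 0.11 at 200 nm,
# 0.14 at 800 nm.  See docs/methods.md for the choice.
DEFAULT_BACKGROUND = BackgroundLine(intercept=0.10, slope=5e-5)


@dataclass
class VaporResponseModel:
    """Whole-wing vapor response of one wing side.

    Precomputes the three single-scale scenario spectra (all-air, B-filled,
    AB-filled) once; every vapor state is then an incoherent mixture plus
    the whole-wing corrections.
    """

    geometry: ScaleGeometry
    media: OpticalMedia = field(default_factory=OpticalMedia)
    background: BackgroundLine = DEFAULT_BACKGROUND
    sigma_nm: float = DEFAULT_SIGMA_NM
    floor: float = DEFAULT_FLOOR
    grid: np.ndarray = field(default_factory=default_grid)

    def __post_init__(self) -> None:
        self.R0, self.RB, self.RAB = scenario_reflectances(self.geometry, self.media, self.grid)
        self._zero = self.whole_wing(FillingState(x=0.0, c_B=0.0, c_AB=0.0, s=0.0))

    def scale_spectrum(self, state: FillingState) -> Spectrum:
        """Single-scale reflectance of the mixed filling state."""
        return mix_spectra(self.R0, self.RB, self.RAB, state)

    def whole_wing(self, state: FillingState) -> Spectrum:
        """Whole-wing reflectance: broadened mixture plus background."""
        return whole_wing_spectrum(self.scale_spectrum(state), self.background, self.sigma_nm)

    @property
    def zero_vapor(self) -> Spectrum:
        """Whole-wing spectrum at zero vapor concentration."""
        return self._zero

    def relative(self, state: FillingState) -> RelativeSpectrum:
        """Relative spectrum of ``state`` against the zero-vapor reference."""
        return relative_spectrum(self.whole_wing(state), self._zero, self.floor)
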