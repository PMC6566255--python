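"""Parametric model of the pepper-pot wing-scale nanoarchitecture.

The scale interior is a stack of "A"/"B" layer pairs: "A" layers are
perforated chitin sheets carrying large quasi-spherical air voids, "B"
layers are thin chitin sheets crossed only by narrow vertical air channels.
The model idealizes one unit cell as cuboids: a central air void of width
``v_xy`` and height ``v_z`` in each A layer, horizontal air channels of
square cross-section ``w_a`` connecting neighboring voids along both
lateral axes, and one vertical channel of square cross-section ``w_b``
through each B layer.

Each layer is reduced to an effective medium via its perforation factor
``P = V_air / (V_air + V_chitin)`` and the volume-weighted index
``n_eff = P * n_void + (1 - P) * n_chitin``.  The main reflectance peak of
the stack sits at ``lambda_main = 2 * p_eff`` with
``p_eff = Re(n_a) * d_a + Re(n_b) * d_b``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ScaleGeometry",
    "OpticalMedia",
    "EffectiveStack",
    "dorsal_geometry",
    "ventral_geometry",
    "default_media",
    "perforation_factor",
    "effective_index",
    "effective_stack",
    "main_peak_wavelength",
    "calibrate_channel_width",
]

_TOL = 1e-9


@dataclass(frozen=True)
class ScaleGeometry:
    """All cuboid dimensions of one wing side's unit cell, in nm.

    ``p_z``, ``v_xy`` and ``v_z`` are derived quantities and must satisfy
    ``p_z = d_a + d_b``, ``v_xy = p_xy - c`` and ``v_z = d_a`` exactly.
    """

    p_xy: float
    p_z: float
    d_a: float
    d_b: float
    w_a: float
    w_b: float
    c: float
    v_xy: float
    v_z: float
    n_stories: int = 4

    def __post_init__(self) -> None:
        for name in ("p_xy", "p_z", "d_a", "d_b", "w_a", "w_b", "c", "v_xy", "v_z"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")
        if self.n_stories < 1:
            raise ValueError("n_stories must be >= 1")
        if abs(self.p_z - (self.d_a + self.d_b)) > _TOL:
            raise ValueError("p_z must equal d_a + d_b")
        if abs(self.v_xy - (self.p_xy - self.c)) > _TOL:
            raise ValueError("v_xy must equal p_xy - c")
        if abs(self.v_z - self.d_a) > _TOL:
            raise ValueError("v_z must equal d_a")
        if self.c > self.p_xy:
            raise ValueError("channel length c must not exceed p_xy")
        if self.w_a > self.v_xy + _TOL or self.w_b > self.v_xy + _TOL:
            raise ValueError("channel width exceeds void width")
        if self.w_a > self.d_a + _TOL:
            raise ValueError("horizontal channel width exceeds A-layer thickness")
        if self.w_b > self.p_xy + _TOL:
            raise ValueError("vertical channel width exceeds cell width")

    @classmethod
    def from_primary(
        cls,
        p_xy: float,
        d_a: float,
        d_b: float,
        w_a: float,
        w_b: float,
        c: float,
        n_stories: int = 4,
    ) -> "ScaleGeometry":
        """Build a geometry from the independent dimensions, deriving the rest."""
        return cls(
            p_xy=p_xy,
            p_z=d_a + d_b,
            d_a=d_a,
            d_b=d_b,
            w_a=w_a,
            w_b=w_b,
            c=c,
            v_xy=p_xy - c,
            v_z=d_a,
            n_stories=n_stories,
        )

    def scaled(self, k: float) -> "ScaleGeometry":
        """Uniformly scale every length by ``k`` (stories unchanged)."""
        if k <= 0:
            raise ValueError("scale factor must be positive")
        return ScaleGeometry.from_primary(
            self.p_xy * k, self.d_a * k, self.d_b * k,
            self.w_a * k, self.w_b * k, self.c * k, self.n_stories,
        )

    def with_channel_width(self, w: float) -> "ScaleGeometry":
        return replace(self, w_a=w, w_b=w)


@dataclass(frozen=True)
class OpticalMedia:
    """Refractive indices of the constituent media."""

    n_chitin: complex = 1.56 + 0.033j
    n_ethanol: float = 1.36
    n_air: float = 1.0

    def __post_init__(self) -> None:
        for name in ("n_chitin", "n_ethanol", "n_air"):
            n = complex(getattr(self, name))
            if n.real < 1:
                raise ValueError(f"Re({name}) must be >= 1")
            if n.imag < 0:
                raise ValueError(f"Im({name}) must be >= 0")


@dataclass(frozen=True)
class EffectiveStack:
    """Per-layer perforation factors and effective indices of one geometry."""

    P_A: float
    P_B: float
    n_a: complex
    n_b: complex
    p_eff: float
    lambda_main: float


def dorsal_geometry(n_stories: int = 4) -> ScaleGeometry:
    """Dorsal (blue) side model dimensions, in nm."""
    return ScaleGeometry.from_primary(200.0, 150.0, 50.0, 100.0, 100.0, 25.0, n_stories)


def ventral_geometry(n_stories: int = 4) -> ScaleGeometry:
    """Ventral (gold-green) side model dimensions, in nm."""
    return ScaleGeometry.from_primary(260.0, 195.0, 65.0, 130.0, 130.0, 32.5, n_stories)


def default_media() -> OpticalMedia:
    return OpticalMedia()


# ---------------------------------------------------------------------------
# perforation factor: union-of-cuboids air volume per unit cell


def _box_volume(box: tuple[np.ndarray, np.ndarray]) -> float:
    lo, hi = box
    ext = np.maximum(hi - lo, 0.0)
    return float(np.prod(ext))


def _box_intersection(boxes) -> tuple[np.ndarray, np.ndarray]:
    los = np.max([b[0] for b in boxes], axis=0)
    his = np.min([b[1] for b in boxes], axis=0)
    return los, his


def _union_volume(boxes) -> float:
    """Volume of a union of axis-aligned boxes by inclusion-exclusion."""
    total = 0.0
    n = len(boxes)
    for k in range(1, n + 1):
        sign = 1.0 if k % 2 == 1 else -1.0
        for subset in combinations(range(n), k):
            total += sign * _box_volume(_box_intersection([boxes[i] for i in subset]))
    return total


def _a_layer_air_boxes(geom: ScaleGeometry) -> list[tuple[np.ndarray, np.ndarray]]:
    """Air cuboids of one A-layer unit cell, coordinates in [0,p_xy]^2 x [0,d_a].

    The central void is centered in the cell; each lateral axis carries a
    horizontal channel of total length 2c centered on the cell boundary, so
    a length c lies at each end of the cell and overlaps the void by c/2.
    """
    p, da, v, w, c = geom.p_xy, geom.d_a, geom.v_xy, geom.w_a, geom.c
    half = p / 2.0
    boxes = []

    def box(x0, x1, y0, y1, z0, z1):
        return (np.array([x0, y0, z0]), np.array([x1, y1, z1]))

    # central void
    boxes.append(box(half - v / 2, half + v / 2,
                     half - v / 2, half + v / 2,
                     da / 2 - geom.v_z / 2, da / 2 + geom.v_z / 2))
    if w > 0 and c > 0:
        zlo, zhi = da / 2 - w / 2, da / 2 + w / 2
        # channels along x (two half-channels of length c at the boundaries)
        boxes.append(box(0.0, c, half - w / 2, half + w / 2, zlo, zhi))
        boxes.append(box(p - c, p, half - w / 2, half + w / 2, zlo, zhi))
        # channels along y
        boxes.append(box(half - w / 2, half + w / 2, 0.0, c, zlo, zhi))
        boxes.append(box(half - w / 2, half + w / 2, p - c, p, zlo, zhi))
    return boxes


def perforation_factor(geom: ScaleGeometry, layer: str) -> float:
    """Air volume fraction ``V_air / (V_air + V_chitin)`` of one layer's cell.

    ``layer`` is ``"A"`` (void + horizontal channels, counted as a union of
    cuboids so the channel/void overlap is not double counted) or ``"B"``
    (one vertical channel of cross-section ``w_b`` x ``w_b``).
    """
    tag = layer.upper()
    if tag == "A":
        cell = geom.p_xy**2 * geom.d_a
        air = _union_volume(_a_layer_air_boxes(geom))
    elif tag == "B":
        cell = geom.p_xy**2 * geom.d_b
        air = geom.w_b**2 * geom.d_b
    else:
        raise ValueError(f"unknown layer tag {layer!r}; expected 'A' or 'B'")
    if cell <= 0:
        raise ValueError("degenerate cell with zero volume")
    P = air / cell
    if not -1e-12 <= P <= 1 + 1e-12:
        raise ValueError(f"perforation factor {P} outside [0, 1]")
    return min(max(P, 0.0), 1.0)


def effective_index(P: float, media: OpticalMedia, void_medium_index: complex | None = None) -> complex:
    """Volume-weighted effective index ``P*n_void + (1-P)*n_chitin``."""
    if not 0.0 <= P <= 1.0:
        raise ValueError(f"perforation factor {P} outside [0, 1]")
    n_void = media.n_air if void_medium_index is None else void_medium_index
    return P * complex(n_void) + (1.0 - P) * complex(media.n_chitin)


def effective_stack(
    geom: ScaleGeometry,
    media: OpticalMedia,
    void_medium_a: complex | None = None,
    void_medium_b: complex | None = None,
) -> EffectiveStack:
    """Perforation factors, effective indices and the main-peak predictor.

    The void media default to air; pass the ethanol index to describe a
    liquid-filled layer.
    """
    P_A = perforation_factor(geom, "A")
    P_B = perforation_factor(geom, "B")
    n_a = effective_index(P_A, media, void_medium_a)
    n_b = effective_index(P_B, media, void_medium_b)
    p_eff = n_a.real * geom.d_a + n_b.real * geom.d_b
    return EffectiveStack(P_A=P_A, P_B=P_B, n_a=n_a, n_b=n_b,
                          p_eff=p_eff, lambda_main=2.0 * p_eff)


def main_peak_wavelength(geom: ScaleGeometry, media: OpticalMedia) -> float:
    """Predicted main reflectance peak ``2 * p_eff`` of the air-filled stack, nm."""
    return effective_stack(geom, media).lambda_main


def calibrate_channel_width(
    geom: ScaleGeometry,
    media: OpticalMedia,
    lambda_target: float,
    tol_nm: float = 0.1,
) -> ScaleGeometry:
    """Find the joint channel width ``w_a = w_b = w*`` placing the main peak
    at ``lambda_target``.

    ``lambda_main`` is strictly decreasing in the channel width (more air
    lowers the effective index), so a bracketed root find suffices.  Raises
    ``ValueError`` reporting the achievable range when the target is outside
    it.
    """
    w_max = min(geom.v_xy, geom.d_a)

    def lam(w: float) -> float:
        return main_peak_wavelength(geom.with_channel_width(w), media)

    lam_hi, lam_lo = lam(0.0), lam(w_max)
    if not (lam_lo - _TOL <= lambda_target <= lam_hi + _TOL):
        raise ValueError(
            f"target {lambda_target} nm outside achievable range "
            f"[{lam_lo:.3f}, {lam_hi:.3f}] nm for w in (0, {w_max}]"
        )
    if abs(lam(geom.w_a) - lambda_target) <= tol_nm and geom.w_a == geom.w_b:
        return geom
    w_star = brentq(lambda w: lam(w) - lambda_target, 0.0, w_max, xtol=1e-6)
    out = geom.with_channel_width(float(w_star))
    assert abs(main_peak_wavelength(out, media) - lambda_target) <= tol_nm
    return out
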