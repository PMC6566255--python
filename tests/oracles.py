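"""Independent oracles: brute-force voxel counting for air-volume fractions
and closed-form thin-film reflectance formulas.

These deliberately avoid the package's analytic code paths: volumes are
counted on a voxel grid, and the film formulas are textbook closed forms.
"""

from __future__ import annotations

import numpy as np


def voxel_perforation(geom, layer: str, resolution: float = 1.0) -> float:
    """Air fraction of one layer's unit cell by voxel counting.

    Voxels of size ``resolution`` nm are marked air if their center lies in
    the central void or any channel segment; the union is counted once by
    construction.
    """
    p = geom.p_xy
    nxy = max(int(round(p / resolution)), 1)
    ax = (np.arange(nxy) + 0.5) * (p / nxy)

    if layer.upper() == "B":
        # one vertical channel of square cross-section w_b, full layer height
        half = p / 2.0
        in_ch = (np.abs(ax - half) <= geom.w_b / 2.0)
        frac_xy = np.outer(in_ch, in_ch).mean()
        return float(frac_xy)  # channel spans the full d_b, so z drops out

    d = geom.d_a
    nz = max(int(round(d / resolution)), 1)
    az = (np.arange(nz) + 0.5) * (d / nz)
    X, Y, Z = np.meshgrid(ax, ax, az, indexing="ij")
    half = p / 2.0
    zc = d / 2.0

    air = (
        (np.abs(X - half) <= geom.v_xy / 2.0)
        & (np.abs(Y - half) <= geom.v_xy / 2.0)
        & (np.abs(Z - zc) <= geom.v_z / 2.0)
    )
    if geom.w_a > 0 and geom.c > 0:
        near_z = np.abs(Z - zc) <= geom.w_a / 2.0
        near_y = np.abs(Y - half) <= geom.w_a / 2.0
        near_x = np.abs(X - half) <= geom.w_a / 2.0
        at_x_edge = (X <= geom.c) | (X >= p - geom.c)
        at_y_edge = (Y <= geom.c) | (Y >= p - geom.c)
        air |= at_x_edge & near_y & near_z
        air |= at_y_edge & near_x & near_z
    return float(air.mean())


def fresnel_interface_reflectance(n0: complex, n1: complex) -> float:
    """Bare-interface reflectance at normal incidence."""
    r = (n0 - n1) / (n0 + n1)
    return float(abs(r) ** 2)


def airy_film_reflectance(n0: complex, n1: complex, n2: complex, d: float,
                          wavelengths: np.ndarray) -> np.ndarray:
    """Single-film (Airy) reflectance at normal incidence, closed form."""
    r01 = (n0 - n1) / (n0 + n1)
    r12 = (n1 - n2) / (n1 + n2)
    phase = np.exp(2j * np.pi * 2.0 * n1 * d / np.asarray(wavelengths, dtype=float))
    r = (r01 + r12 * phase) / (1.0 + r01 * r12 * phase)
    return np.abs(r) ** 2


def random_valid_geometry(rng: np.random.Generator, n_stories: int = 4,
                          lambda_window: tuple[float, float] = (340.0, 740.0)):
    """Random geometry with its main peak inside the visible grid."""
    from pepperpot.geometry import OpticalMedia, ScaleGeometry, effective_stack

    media = OpticalMedia(n_chitin=1.56 + 0j)
    while True:
        p_xy = rng.uniform(150, 300)
        d_a = rng.uniform(100, 200)
        d_b = rng.uniform(30, 80)
        c = rng.uniform(0.08, 0.25) * p_xy
        w = rng.uniform(0.2, 0.7) * min(p_xy - c, d_a)
        try:
            geom = ScaleGeometry.from_primary(p_xy, d_a, d_b, w, w, c, n_stories)
        except ValueError:
            continue
        lam = effective_stack(geom, media).lambda_main
        if lambda_window[0] < lam < lambda_window[1]:
            return geom
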