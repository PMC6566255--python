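"""Seeded synthetic inputs: TEM-like cross sections with ground truth, and
vapor-series relative spectra from the forward model with noise.

The image generator renders the cuboid scale model as a TEM projection
would show it — alternating perforated ("A") and thin ("B") chitin bands,
bright elliptical air voids, mid-gray channel marks (partial-thickness air
in the 70 nm slice projects as a lighter gray), sinusoidal layer waviness,
neighbor-spacing jitter and additive sensor noise.  Every generator is a
pure function of its parameters and seed, and returns the ground truth it
rendered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .dsa import VoidMap
from .geometry import OpticalMedia, ScaleGeometry
from .optics import RelativeSpectrum
from .pipeline import VaporResponseModel
from .vaporfit import FitCoefficients
from .wholewing import BackgroundLine

__all__ = [
    "ImageDisorderParams",
    "SpectraSeriesParams",
    "TemGroundTruth",
    "generate_tem_image",
    "generate_spectra_series",
    "GRAY_CHITIN",
    "GRAY_CHANNEL",
    "GRAY_VOID",
]

GRAY_CHITIN = 60.0
GRAY_CHANNEL = 150.0
GRAY_VOID = 230.0

_MARGIN_PX = 12


@dataclass(frozen=True)
class ImageDisorderParams:
    """Disorder knobs of the synthetic TEM render.

    ``spacing_jitter`` is the std of the neighbor distance as a fraction of
    the lateral period; ``channel_correlation`` places the B-layer vertical
    channels either above the walls between the middle layer's voids
    (``above_wall``, the signature seen in real sections) or uniformly at
    random (``random``).
    """

    spacing_jitter: float = 0.0
    waviness_amplitude: float = 0.0
    waviness_period: float = 400.0
    channel_correlation: str = "above_wall"
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.spacing_jitter <= 0.5:
            raise ValueError("spacing_jitter must be in [0, 0.5]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.waviness_period <= 0:
            raise ValueError("waviness_period must be positive")
        if self.channel_correlation not in ("above_wall", "random"):
            raise ValueError("channel_correlation must be 'above_wall' or 'random'")


@dataclass(frozen=True)
class TemGroundTruth:
    """Everything the renderer knows about the image it produced."""

    voids: VoidMap                       # centers of the middle A layer
    void_axes_px: tuple[float, float]    # ellipse diameters (lateral, vertical)
    channel_x_px: dict[str, np.ndarray]  # per B-layer vertical channel positions
    band_rows: dict[str, tuple[int, int]]  # per-band (row_min, row_max)
    spacing_px: float                    # nominal lateral period


def _band_layout(geom: ScaleGeometry, pixel_scale: float) -> tuple[dict[str, tuple[int, int]], int]:
    """Rows of the B1 A1 B2 A2 B3 A3 B4 band sequence (top to bottom)."""
    da = int(round(geom.d_a / pixel_scale))
    db = int(round(geom.d_b / pixel_scale))
    rows: dict[str, tuple[int, int]] = {}
    r = _MARGIN_PX
    for i in range(1, 4):
        rows[f"B{i}"] = (r, r + db)
        r += db
        rows[f"A{i}"] = (r, r + da)
        r += da
    rows["B4"] = (r, r + db)
    r += db
    return rows, r + _MARGIN_PX


def _jittered_positions(rng: np.random.Generator, start: float, spacing: float,
                        jitter: float, n: int, min_spacing: float) -> np.ndarray:
    """Jittered lattice positions with a hard wall: voids are distinct
    cavities separated by chitin, so neighbor spacings never fall below the
    void diameter (resampled until satisfied)."""
    steps = np.empty(n - 1)
    for i in range(n - 1):
        s = spacing * (1.0 + jitter * rng.standard_normal())
        while s < min_spacing:
            s = spacing * (1.0 + jitter * rng.standard_normal())
        steps[i] = s
    return start + np.concatenate([[0.0], np.cumsum(steps)])


def _draw_ellipse(img: np.ndarray, cx: float, cy: float, rx: float, ry: float,
                  value: float) -> None:
    x0, x1 = int(max(cx - rx - 1, 0)), int(min(cx + rx + 2, img.shape[1]))
    y0, y1 = int(max(cy - ry - 1, 0)), int(min(cy + ry + 2, img.shape[0]))
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1)
    ys = np.arange(y0, y1)
    XX, YY = np.meshgrid(xs, ys)
    mask = ((XX - cx) / rx) ** 2 + ((YY - cy) / ry) ** 2 <= 1.0
    img[y0:y1, x0:x1][mask] = value


def generate_tem_image(
    geom: ScaleGeometry,
    params: ImageDisorderParams,
    pixel_scale: float = 2.0,
    n_voids: int = 20,
) -> tuple[np.ndarray, TemGroundTruth]:
    """Render a cross-sectional TEM-like image of the layered void lattice.

    Returns the uint8 image and the ground truth (void centers of the
    middle A layer with waviness applied, ellipse axes, per-B-layer channel
    positions, band rows).  ``pixel_scale`` is nm per pixel.
    """
    if n_voids < 3:
        raise ValueError("need at least 3 voids")
    p_px = geom.p_xy / pixel_scale
    rx = geom.v_xy / 2.0 / pixel_scale
    ry = geom.v_z / 2.0 / pixel_scale
    if 2 * min(rx, ry) < 3:
        raise ValueError("pixel_scale too coarse: voids smaller than 3 px")
    wa_px = geom.w_a / pixel_scale
    wb_px = geom.w_b / pixel_scale

    rng = np.random.default_rng(params.seed)
    rows, height = _band_layout(geom, pixel_scale)
    width = int(round((n_voids + 1) * p_px))
    flat = np.full((height, width), GRAY_CHITIN, dtype=float)

    # void x positions per A layer; adjacent layers staggered by half a period
    centers_by_layer: dict[str, np.ndarray] = {}
    for i, name in enumerate(("A1", "A2", "A3")):
        start = p_px if i == 1 else p_px / 2.0
        xs = _jittered_positions(rng, start, p_px, params.spacing_jitter, n_voids,
                                 min_spacing=2.0 * rx + 2.0)
        centers_by_layer[name] = xs[(xs > rx) & (xs < width - rx)]

    mid_centers = centers_by_layer["A2"]
    walls = 0.5 * (mid_centers[:-1] + mid_centers[1:])

    # horizontal channel bars between adjacent voids, then the voids on top
    for name in ("A1", "A2", "A3"):
        r0, r1 = rows[name]
        zc = (r0 + r1) / 2.0
        xs = centers_by_layer[name]
        z0 = int(round(zc - wa_px / 2.0))
        z1 = int(round(zc + wa_px / 2.0))
        # the channel network continues past the rendered voids on both sides
        segments = [(0.0, xs[0])] + list(zip(xs[:-1], xs[1:])) + [(xs[-1], float(width))]
        for xa, xb in segments:
            flat[z0:z1, int(round(xa)): int(round(xb))] = GRAY_CHANNEL
        for x in xs:
            _draw_ellipse(flat, x, zc, rx, ry, GRAY_VOID)

    # vertical channels crossing the B layers
    channel_x: dict[str, np.ndarray] = {}
    for name in ("B1", "B2", "B3", "B4"):
        r0, r1 = rows[name]
        if params.channel_correlation == "above_wall":
            xs = walls.copy()
        else:
            xs = np.sort(rng.uniform(rx, width - rx, size=len(walls)))
        channel_x[name] = xs
        for x in xs:
            x0 = int(round(x - wb_px / 2.0))
            x1 = int(round(x + wb_px / 2.0))
            flat[r0:r1, max(x0, 0): min(x1, width)] = GRAY_CHANNEL

    # sinusoidal layer waviness: shift every column vertically
    cols = np.arange(width, dtype=float)
    dz = params.waviness_amplitude * np.sin(2.0 * np.pi * cols / params.waviness_period)
    if params.waviness_amplitude != 0.0:
        rr = np.arange(height, dtype=float)
        RR, CC = np.meshgrid(rr, cols, indexing="ij")
        src_rows = RR - dz[None, :]
        wavy = map_coordinates(flat, [src_rows.ravel(), CC.ravel()], order=1,
                               mode="nearest").reshape(height, width)
    else:
        wavy = flat

    if params.noise_sigma > 0:
        wavy = wavy + params.noise_sigma * rng.standard_normal(wavy.shape)
    image = np.clip(wavy, 0, 255).astype(np.uint8)

    r0, r1 = rows["A2"]
    zc = (r0 + r1) / 2.0
    gt_centers = np.column_stack([
        mid_centers,
        zc + np.interp(mid_centers, cols, dz),
    ])
    truth = TemGroundTruth(
        voids=VoidMap(centers=gt_centers, pixel_scale=pixel_scale),
        void_axes_px=(2 * rx, 2 * ry),
        channel_x_px=channel_x,
        band_rows=rows,
        spacing_px=p_px,
    )
    return image, truth


@dataclass(frozen=True)
class SpectraSeriesParams:
    """Ground-truth coefficient law, concentration list and noise of a series."""

    coefficients: FitCoefficients
    x_values: tuple[float, ...] = (0.125, 0.25, 0.375, 0.5)
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0.0 <= x <= 1.0 for x in self.x_values):
            raise ValueError("x_values must lie in [0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def generate_spectra_series(
    geom: ScaleGeometry,
    media: OpticalMedia,
    bg: BackgroundLine,
    sigma: float,
    params: SpectraSeriesParams,
) -> list[tuple[float, RelativeSpectrum]]:
    """Vapor-series relative spectra from the forward chain, with noise.

    For each concentration the filling state follows the linear-in-x
    coefficient law; the relative spectrum is formed against the zero-vapor
    whole-wing reference and multiplied by unit-mean lognormal noise with
    coefficient of variation ``noise_cv`` (relative spectra are positive by
    construction, so the noise must be too).
    """
    model = VaporResponseModel(geometry=geom, media=media, background=bg, sigma_nm=sigma)
    rng = np.random.default_rng(params.seed)
    series: list[tuple[float, RelativeSpectrum]] = []
    for x in params.x_values:
        rel = model.relative(params.coefficients.state_at(x))
        values = rel.values
        if params.noise_cv > 0:
            sig = np.sqrt(np.log1p(params.noise_cv**2))
            noise = rng.lognormal(mean=-0.5 * sig**2, sigma=sig, size=values.shape)
            values = values * noise
        series.append((x, RelativeSpectrum(rel.wavelengths, values)))
    return series
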