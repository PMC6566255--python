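"""Direct-space averaging (DSA) of cross-sectional TEM images.

A quasi-ordered void lattice has no global registration: layers undulate
and the neighbor spacing jitters.  DSA recovers the mean local environment
of the voids of one "A" layer by, for each void, shifting the image so the
void sits at the origin, rotating so the left/right-neighbor chord is
horizontal, rescaling so the neighbor distance is common to all
sub-images, and averaging the gray values pixel by pixel.  Linecuts along
rows of the averaged image then expose correlations between the air
network of adjacent layers (e.g., vertical channels sitting above the
walls between voids).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from skimage.feature import peak_local_max

__all__ = [
    "VoidMap",
    "DSAResult",
    "detect_void_centers",
    "dsa_average",
    "linecut",
    "default_window",
    "autocorrelation_at_lag",
    "wall_alignment_score",
]


@dataclass(frozen=True)
class VoidMap:
    """Void centers of the annotated (middle) A layer, sorted left to right.

    ``centers`` is (n, 2) float array of (x, z) pixel positions.  At least
    three centers are required: every averaged void needs both neighbors.
    """

    centers: np.ndarray
    pixel_scale: float = 1.0

    def __post_init__(self) -> None:
        c = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if c.ndim != 2 or c.shape[1] != 2:
            raise ValueError("centers must be an (n, 2) array of (x, z) positions")
        if c.shape[0] < 3:
            raise ValueError(f"need >= 3 void centers for averaging, got {c.shape[0]}")
        order = np.argsort(c[:, 0])
        object.__setattr__(self, "centers", c[order])
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")

    def __len__(self) -> int:
        return len(self.centers)


@dataclass
class DSAResult:
    """Averaged local environment and its bookkeeping.

    ``averaged_image`` holds mean gray values in the input image's units;
    the window origin (the averaged void center) is the central pixel.
    ``coverage`` counts, per pixel, how many sub-images sampled inside the
    source image bounds.  Linecuts are rescaled to [0, 1].
    """

    averaged_image: np.ndarray
    n_averaged: int
    reference_distance: float
    coverage: np.ndarray
    linecuts: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def center(self) -> tuple[int, int]:
        """(row, col) of the averaged void center."""
        return self.averaged_image.shape[0] // 2, self.averaged_image.shape[1] // 2


def detect_void_centers(
    image: np.ndarray,
    expected_spacing: float,
    band: tuple[int, int],
    pixel_scale: float = 1.0,
    rel_threshold: float = 0.65,
    band_margin: float = 0.2,
) -> VoidMap:
    """Bright-blob detection of void centers inside a horizontal band.

    The band (extended vertically by ``band_margin`` of its height, so that
    layer waviness does not clip the blobs) is smoothed with
    sigma = expected_spacing / 8 and local maxima separated by at least half
    the expected spacing are kept, then refined to intensity centroids.
    Voids image bright in these TEM sections; detection is always of bright
    blobs.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D grayscale image")
    r0, r1 = band
    if not (0 <= r0 < r1 <= img.shape[0]):
        raise ValueError("band outside image")
    margin = int(round(band_margin * (r1 - r0)))
    r0 = max(r0 - margin, 0)
    r1 = min(r1 + margin, img.shape[0])
    sub = img[r0:r1]
    smooth = gaussian_filter(sub, sigma=expected_spacing / 8.0, mode="nearest")
    lo, hi = smooth.min(), smooth.max()
    if hi <= lo:
        raise ValueError("need >= 3 void centers for averaging, got 0 (blank band)")
    thr = lo + rel_threshold * (hi - lo)
    peaks = peak_local_max(
        smooth,
        min_distance=max(int(expected_spacing / 2), 1),
        threshold_abs=thr,
        exclude_border=False,
    )
    if len(peaks) < 3:
        raise ValueError(f"need >= 3 void centers for averaging, got {len(peaks)}")
    # refine by intensity-weighted centroid: the voids span the band
    # vertically, so the raw peak row is degenerate under noise
    centers = []
    halfcol = max(int(expected_spacing / 6), 2)
    rows_idx = np.arange(sub.shape[0], dtype=float)
    for prow, pcol in peaks:
        c0, c1 = max(pcol - halfcol, 0), min(pcol + halfcol + 1, sub.shape[1])
        patch = np.maximum(smooth[:, c0:c1] - thr, 0.0)
        total = patch.sum()
        if total <= 0:
            centers.append((float(pcol), float(prow)))
            continue
        zc = float((patch.sum(axis=1) * rows_idx).sum() / total)
        cols_idx = np.arange(c0, c1, dtype=float)
        xc = float((patch.sum(axis=0) * cols_idx).sum() / total)
        centers.append((xc, zc))
    centers = np.asarray(centers) + [0.0, r0]
    return VoidMap(centers=centers, pixel_scale=pixel_scale)


def default_window(voids: VoidMap, d_a_px: float, d_b_px: float) -> tuple[int, int]:
    """Default sub-image window: 1.5 median spacings wide, 1.2*(d_a+2*d_b) tall."""
    d = np.linalg.norm(np.diff(voids.centers, axis=0), axis=1)
    width = int(round(1.5 * np.median(d)))
    height = int(round(1.2 * (d_a_px + 2.0 * d_b_px)))
    return width | 1, height | 1  # odd sizes keep the void on a pixel center


def dsa_average(
    image: np.ndarray,
    voids: VoidMap,
    window: tuple[int, int],
) -> DSAResult:
    """Shift / rotate / scale registration and pixelwise averaging.

    For every interior void (endpoints are excluded — each averaged void
    needs both neighbors) the neighbor chord length ``d`` and angle
    ``alpha`` are measured; the sub-image is sampled in the void-local
    frame (translated to the void, rotated by ``-alpha``, rescaled so ``d``
    maps to the median neighbor distance) with bilinear interpolation, and
    all sub-images are averaged.  Samples falling outside the source image
    take the nearest edge value and are flagged in the coverage map.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D grayscale image")
    width, height = int(window[0]), int(window[1])
    if width >= img.shape[1] or height >= img.shape[0]:
        raise ValueError("window must be smaller than the image")
    centers = voids.centers
    chords = centers[2:] - centers[:-2]  # right neighbor minus left neighbor
    d_all = np.linalg.norm(chords, axis=1)
    d_ref = float(np.median(d_all))

    half_w, half_h = width // 2, height // 2
    u = np.arange(-half_w, width - half_w, dtype=float)
    v = np.arange(-half_h, height - half_h, dtype=float)
    UU, VV = np.meshgrid(u, v)  # (height, width)

    acc = np.zeros((height, width), dtype=float)
    cover = np.zeros((height, width), dtype=int)
    for i in range(1, len(centers) - 1):
        dx, dz = chords[i - 1]
        d = d_all[i - 1]
        alpha = np.arctan2(dz, dx)
        scale = d / d_ref  # window frame -> image frame magnification
        ca, sa = np.cos(alpha), np.sin(alpha)
        x = centers[i, 0] + scale * (ca * UU - sa * VV)
        z = centers[i, 1] + scale * (sa * UU + ca * VV)
        inside = (x >= 0) & (x <= img.shape[1] - 1) & (z >= 0) & (z <= img.shape[0] - 1)
        sampled = map_coordinates(img, [z.ravel(), x.ravel()], order=1, mode="nearest")
        acc += sampled.reshape(height, width)
        cover += inside.astype(int)
    n = len(centers) - 2
    averaged = acc / n
    return DSAResult(
        averaged_image=averaged,
        n_averaged=n,
        reference_distance=d_ref,
        coverage=cover,
    )


def linecut(result: DSAResult, row_label: str, row: int) -> np.ndarray:
    """Row intensity profile rescaled so min -> 0 and max -> 1.

    A constant row has no dynamic range: it is returned as zeros and the
    stored linecut is flagged by the label suffix ``(flat)``.
    """
    img = result.averaged_image
    if not 0 <= row < img.shape[0]:
        raise ValueError("row outside the averaged image")
    profile = img[row].astype(float)
    span = profile.max() - profile.min()
    if span == 0:
        out = np.zeros_like(profile)
        result.linecuts[f"{row_label} (flat)"] = out
        return out
    out = (profile - profile.min()) / span
    result.linecuts[row_label] = out
    return out


def autocorrelation_at_lag(profile: np.ndarray, lag: int, detrend_sigma: float | None = None) -> float:
    """Pearson correlation of a profile with itself shifted by ``lag`` pixels.

    With ``detrend_sigma`` a Gaussian-smoothed baseline of that width is
    subtracted first, so slow intensity ramps do not masquerade as
    quasi-periodicity at the lattice spacing.
    """
    p = np.asarray(profile, dtype=float)
    lag = int(round(lag))
    if lag <= 0 or lag >= p.size - 2:
        raise ValueError("lag must be positive and shorter than the profile")
    if detrend_sigma is not None:
        from scipy.ndimage import gaussian_filter1d

        p = p - gaussian_filter1d(p, detrend_sigma, mode="nearest")
    a, b = p[:-lag], p[lag:]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def wall_alignment_score(
    result: DSAResult,
    row: int,
    halfwidth: int = 3,
) -> float:
    """Contrast of a row's intensity above the void walls vs above the voids.

    The reference distance spans the left-to-right neighbor chord, i.e. two
    lattice spacings; walls between voids therefore sit at odd multiples of
    a quarter of it from the averaged void center, and voids at even
    multiples.  The score is the mean profile value in small windows around
    the wall positions minus the mean around the void positions, scaled by
    the row's dynamic range.  Positive scores mean the air channels in that
    row correlate with the walls; near zero means no alignment.
    """
    profile = result.averaged_image[row].astype(float)
    ncols = profile.size
    c = ncols // 2
    a = result.reference_distance / 2.0  # one lattice spacing
    wall_cols = [c - 1.5 * a, c - 0.5 * a, c + 0.5 * a, c + 1.5 * a]
    void_cols = [c - a, c, c + a]

    def mean_at(cols):
        vals = []
        for col in cols:
            k = int(round(col))
            if halfwidth <= k < ncols - halfwidth:
                vals.append(profile[k - halfwidth: k + halfwidth + 1].mean())
        return np.mean(vals) if vals else np.nan

    span = profile.max() - profile.min()
    if span == 0:
        return 0.0
    return float((mean_at(wall_cols) - mean_at(void_cols)) / span)
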