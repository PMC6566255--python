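import numpy as np
import pytest
from scipy.ndimage import map_coordinates
from scipy.spatial import cKDTree

from pepperpot.dsa import (
    VoidMap,
    autocorrelation_at_lag,
    default_window,
    detect_void_centers,
    dsa_average,
    linecut,
    wall_alignment_score,
)
from pepperpot.synth import ImageDisorderParams, generate_tem_image

WINDOW = (151, 151)


def make_image(dorsal, **kwargs):
    params = ImageDisorderParams(**kwargs)
    return generate_tem_image(dorsal, params, pixel_scale=2.0, n_voids=20)


def sample_environment(image, center, window):
    """Bilinear sub-image around a (possibly fractional) center."""
    w, h = window
    u = np.arange(w, dtype=float) - w // 2
    v = np.arange(h, dtype=float) - h // 2
    UU, VV = np.meshgrid(u, v)
    return map_coordinates(
        image.astype(float),
        [(center[1] + VV).ravel(), (center[0] + UU).ravel()],
        order=1, mode="nearest",
    ).reshape(h, w)


class TestDetectVoidCenters:
    def test_clean_image_centers_within_one_pixel(self, dorsal):
        img, truth = make_image(dorsal, seed=3)
        found = detect_void_centers(img, truth.spacing_px, truth.band_rows["A2"])
        dist, _ = cKDTree(truth.voids.centers).query(found.centers)
        assert len(found) == len(truth.voids)
        assert dist.max() < 1.0

    def test_blank_image_raises(self):
        with pytest.raises(ValueError, match=">= 3"):
            detect_void_centers(np.zeros((200, 600)), 100.0, (50, 150))

    @pytest.mark.parametrize("seed", [7, 11, 23])
    def test_jittered_noisy_benchmark(self, dorsal, seed):
        """20% spacing jitter plus sensor noise: nearly all detected centers
        stay within 2 px of the rendered truth."""
        params = ImageDisorderParams(spacing_jitter=0.2, waviness_amplitude=10.0,
                                     waviness_period=500.0, noise_sigma=5.0, seed=seed)
        img, truth = generate_tem_image(dorsal, params, 2.0, 25)
        found = detect_void_centers(img, truth.spacing_px, truth.band_rows["A2"])
        dist, _ = cKDTree(truth.voids.centers).query(found.centers)
        assert (dist <= 2.0).mean() >= 0.95

    def test_fewer_than_three_centers_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            VoidMap(centers=np.array([[10.0, 5.0], [30.0, 5.0]]))


class TestDsaAverage:
    def test_periodic_lattice_average_equals_one_period(self, dorsal):
        """With zero disorder every local environment is identical, so the
        average reproduces a single period's environment."""
        img, truth = make_image(dorsal, seed=0)
        result = dsa_average(img, truth.voids, WINDOW)
        expected = sample_environment(img, truth.voids.centers[10], WINDOW)
        rms = np.sqrt(np.mean((result.averaged_image - expected) ** 2))
        assert rms < 0.02 * (img.max() - img.min())
        assert result.n_averaged == len(truth.voids) - 2  # endpoints excluded

    def test_three_identical_voids_return_central_environment(self, dorsal):
        img, truth = generate_tem_image(dorsal, ImageDisorderParams(seed=0), 2.0, 3)
        result = dsa_average(img, truth.voids, (101, 101))
        expected = sample_environment(img, truth.voids.centers[1], (101, 101))
        rms = np.sqrt(np.mean((result.averaged_image - expected) ** 2))
        assert rms < 1.0  # gray levels; interpolation only

    def test_translation_equivariance(self, dorsal):
        """Shifting the whole image (with its annotations) leaves the
        void-local average unchanged."""
        img, truth = make_image(dorsal, seed=4)
        shift = 7
        shifted = np.roll(img, shift, axis=1)
        voids_shifted = VoidMap(truth.voids.centers + [shift, 0.0])
        r1 = dsa_average(img, truth.voids, WINDOW)
        r2 = dsa_average(shifted, voids_shifted, WINDOW)
        interior = (slice(10, -10), slice(10, -10))
        assert np.allclose(r1.averaged_image[interior], r2.averaged_image[interior],
                           atol=1e-9)

    def test_waviness_transformed_out(self, dorsal):
        """Sinusoidal layer waviness is registered away: the averaged void
        ellipse axes match the rendered truth within 5%."""
        params = ImageDisorderParams(spacing_jitter=0.1, waviness_amplitude=10.0,
                                     waviness_period=500.0, noise_sigma=3.0, seed=5)
        img, truth = generate_tem_image(dorsal, params, 2.0, 25)
        result = dsa_average(img, truth.voids, WINDOW)
        r0, c0 = result.center
        row = result.averaged_image[r0]
        col = result.averaged_image[:, c0]

        def fwhm(profile, center):
            half = (profile[center] + profile.min()) / 2.0
            i = center
            while profile[i] >= half:
                i -= 1
            j = center
            while profile[j] >= half:
                j += 1
            left = i + (half - profile[i]) / (profile[i + 1] - profile[i])
            right = j - (half - profile[j]) / (profile[j - 1] - profile[j])
            return right - left

        lat, vert = truth.void_axes_px
        assert fwhm(row, c0) == pytest.approx(lat, rel=0.05)
        assert fwhm(col, r0) == pytest.approx(vert, rel=0.05)

    def test_window_must_fit_image(self, dorsal):
        img, truth = make_image(dorsal, seed=0)
        with pytest.raises(ValueError, match="window"):
            dsa_average(img, truth.voids, (img.shape[1] + 10, 51))

    def test_default_window_dimensions(self, dorsal):
        img, truth = make_image(dorsal, seed=0)
        w, h = default_window(truth.voids, d_a_px=75.0, d_b_px=25.0)
        assert w % 2 == 1 and h % 2 == 1
        assert w == pytest.approx(1.5 * 100, abs=2)
        assert h == pytest.approx(1.2 * 125, abs=2)


class TestLinecut:
    def test_center_row_normalized_with_peak_at_center(self, dorsal):
        img, truth = make_image(dorsal, seed=0)
        result = dsa_average(img, truth.voids, WINDOW)
        prof = linecut(result, "A2", result.center[0])
        assert prof.min() == 0.0 and prof.max() == 1.0
        # the averaged void is a bright plateau centered on the window axis
        assert prof[result.center[1]] == pytest.approx(1.0, abs=1e-9)
        plateau = np.flatnonzero(prof > 0.9)
        central = plateau[np.abs(plateau - result.center[1]) < 60]
        assert central.mean() == pytest.approx(result.center[1], abs=2)

    def test_constant_row_flagged_as_zeros(self):
        from pepperpot.dsa import DSAResult

        res = DSAResult(averaged_image=np.ones((11, 21)), n_averaged=3,
                        reference_distance=10.0, coverage=np.ones((11, 21), int))
        prof = linecut(res, "flatrow", 5)
        assert np.all(prof == 0.0)
        assert "flatrow (flat)" in res.linecuts


class TestChannelCorrelationSignature:
    """Vertical channels placed above the void walls leave a quasi-periodic
    trace in the averaged B-layer rows; randomly placed channels do not."""

    @staticmethod
    def b_row_stats(dorsal, correlation, seed):
        params = ImageDisorderParams(spacing_jitter=0.08, waviness_amplitude=3.0,
                                     waviness_period=500.0,
                                     channel_correlation=correlation,
                                     noise_sigma=5.0, seed=seed)
        img, truth = generate_tem_image(dorsal, params, 2.0, 30)
        result = dsa_average(img, truth.voids, (301, 171))
        spacing = result.reference_distance / 2.0
        offs = 50  # (d_a + d_b)/2 at 2 nm/px: center of the adjacent B bands
        acs, aligns = [], []
        for row in (result.center[0] - offs, result.center[0] + offs):
            prof = linecut(result, f"B{row}", row)
            acs.append(autocorrelation_at_lag(prof, int(round(spacing)),
                                              detrend_sigma=spacing / 2))
            aligns.append(wall_alignment_score(result, row))
        return float(np.mean(acs)), float(np.mean(aligns))

    def test_correlated_channels_show_quasi_periodicity(self, dorsal):
        ac, align = self.b_row_stats(dorsal, "above_wall", seed=9)
        assert ac > 0.9
        assert align > 0.8

    def test_random_channels_show_no_alignment(self, dorsal):
        ac, align = self.b_row_stats(dorsal, "random", seed=9)
        assert ac < 0.8
        assert abs(align) < 0.3
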