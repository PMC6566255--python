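import numpy as np
import pytest

from pepperpot.optics import FillingState, RelativeSpectrum, Spectrum, default_grid
from pepperpot.pipeline import DEFAULT_BACKGROUND, VaporResponseModel
from pepperpot.synth import SpectraSeriesParams, generate_spectra_series
from pepperpot.vaporfit import (
    DORSAL_ETHANOL_LAW,
    VENTRAL_ETHANOL_LAW,
    FitCoefficients,
    NonIdentifiableModelError,
    filling_factors,
    fit_state,
    linearize_in_x,
    peak_shift,
    peak_wavelength,
    residual_integral,
)

GRID = default_grid()


class TestResidualIntegral:
    def test_identical_spectra_give_zero(self, dorsal_model):
        rel = dorsal_model.relative(FillingState(0.5, 0.04, 0.04, 0.008))
        assert residual_integral(rel, rel) == 0.0

    def test_constant_difference_closed_form(self):
        a = Spectrum(GRID, np.full_like(GRID, 0.5))
        b = Spectrum(GRID, np.full_like(GRID, 0.51))
        assert residual_integral(a, b, 200.0, 800.0) == pytest.approx(0.01**2 * 600.0)

    def test_triangle_difference_matches_analytic_integral(self):
        # difference rises linearly 0 -> h over [400, 500] and back over [500, 600]
        h = 0.02
        diff = np.interp(GRID, [400, 500, 600], [0, h, 0])
        a = Spectrum(GRID, np.ones_like(GRID))
        b = Spectrum(GRID, np.ones_like(GRID) + diff)
        # integral of (h*t)^2 over the two 100 nm ramps = 2 * h^2 * 100 / 3
        assert residual_integral(a, b) == pytest.approx(2 * h**2 * 100 / 3, rel=1e-3)

    def test_window_outside_grid_rejected(self):
        a = Spectrum(GRID, np.ones_like(GRID))
        with pytest.raises(ValueError, match="window"):
            residual_integral(a, a, 100.0, 800.0)


class TestFitState:
    def test_unit_relative_spectrum_fits_to_zero_state(self, dorsal_model):
        flat = RelativeSpectrum(GRID, np.ones_like(GRID))
        state = fit_state(flat, dorsal_model.relative, x_fit=0.5)
        assert state.c_B == pytest.approx(0.0, abs=1e-6)
        assert state.c_AB == pytest.approx(0.0, abs=1e-6)
        assert state.s == pytest.approx(0.0, abs=1e-6)

    def test_noise_free_round_trip_recovers_dorsal_parameters(self, dorsal_model):
        truth = FillingState(0.5, 0.04, 0.04, 0.008)
        measured = dorsal_model.relative(truth)
        state = fit_state(measured, dorsal_model.relative, x_fit=0.5)
        assert state.c_B == pytest.approx(truth.c_B, abs=1e-3)
        assert state.c_AB == pytest.approx(truth.c_AB, abs=1e-3)
        assert state.s == pytest.approx(truth.s, abs=1e-3)
        # optimizer sanity: no worse than the truth
        fitted = residual_integral(measured, dorsal_model.relative(state))
        at_truth = residual_integral(measured, dorsal_model.relative(truth))
        assert fitted <= at_truth + 1e-12

    def test_noisy_recovery_within_monte_carlo_tolerance(self, ventral, media):
        truth_law = FitCoefficients(cB_slope=0.4, cAB_slope=0.0, s_slope=0.012)
        model = VaporResponseModel(ventral)
        series = generate_spectra_series(
            ventral, media, DEFAULT_BACKGROUND, 15.0,
            SpectraSeriesParams(coefficients=truth_law, x_values=(0.5,),
                                noise_cv=0.001, seed=11))
        _, measured = series[0]
        state = fit_state(measured, model.relative, x_fit=0.5)
        assert state.c_B == pytest.approx(0.2, abs=0.02)
        assert state.c_AB == pytest.approx(0.0, abs=0.02)
        assert state.s == pytest.approx(0.006, abs=0.001)

    def test_round_trip_over_random_states(self, dorsal_model, rng):
        for _ in range(8):
            truth = FillingState(
                x=0.5,
                c_B=float(rng.uniform(0.0, 0.3)),
                c_AB=float(rng.uniform(0.0, 0.2)),
                s=float(rng.uniform(0.0, 0.02)),
            )
            measured = dorsal_model.relative(truth)
            state = fit_state(measured, dorsal_model.relative, x_fit=0.5)
            assert state.c_B == pytest.approx(truth.c_B, abs=1e-3)
            assert state.c_AB == pytest.approx(truth.c_AB, abs=1e-3)
            assert state.s == pytest.approx(truth.s, abs=1e-3)

    def test_degenerate_forward_model_flagged(self):
        flat = RelativeSpectrum(GRID, np.ones_like(GRID))

        def forward(state):
            return RelativeSpectrum(GRID, np.ones_like(GRID))

        with pytest.raises(NonIdentifiableModelError):
            fit_state(flat, forward, x_fit=0.5)


class TestLinearLaw:
    def test_published_dorsal_slopes(self):
        coeffs = linearize_in_x(FillingState(0.5, 0.04, 0.04, 0.008), 0.5)
        assert (coeffs.cB_slope, coeffs.cAB_slope, coeffs.s_slope) == (0.08, 0.08, 0.016)

    def test_published_ventral_slopes(self):
        coeffs = linearize_in_x(FillingState(0.5, 0.2, 0.0, 0.006), 0.5)
        assert (coeffs.cB_slope, coeffs.cAB_slope, coeffs.s_slope) == (0.4, 0.0, 0.012)

    def test_zero_state_gives_zero_slopes(self):
        coeffs = linearize_in_x(FillingState(0.5, 0.0, 0.0, 0.0), 0.5)
        assert (coeffs.cB_slope, coeffs.cAB_slope, coeffs.s_slope) == (0.0, 0.0, 0.0)

    def test_zero_x_fit_rejected(self):
        with pytest.raises(ValueError):
            linearize_in_x(FillingState(0.0, 0.0, 0.0, 0.0), 0.0)

    def test_filling_factors(self):
        assert filling_factors(FillingState(0.5, 0.04, 0.04, 0.0)) == (0.04, 0.08)
        assert filling_factors(FillingState(0.5, 0.2, 0.0, 0.0)) == (0.0, 0.2)
        assert filling_factors(FillingState(0.0, 0.0, 0.0, 0.0)) == (0.0, 0.0)


class TestPeakShift:
    def test_identical_spectra_shift_zero(self, dorsal_model):
        assert peak_shift(dorsal_model.zero_vapor, dorsal_model.zero_vapor) == 0.0

    def test_resampled_spectrum_shifts_by_s_times_peak(self, dorsal_model):
        spec = dorsal_model.zero_vapor
        lam0 = peak_wavelength(spec)
        s = 0.01
        shifted = Spectrum(spec.wavelengths, spec.at(spec.wavelengths / (1 + s)))
        assert peak_shift(shifted, spec) == pytest.approx(s * lam0, rel=0.1)

    def test_asymmetric_peak_recovered_subgrid(self):
        # skewed peak, then a known sub-grid shift by spectral resampling
        base = np.exp(-((GRID - 500.0) / 30.0) ** 2) * (1 + 0.002 * (GRID - 500.0))
        spec = Spectrum(GRID, base)
        delta = 3.3
        shifted = Spectrum(GRID, spec.at(GRID - delta))
        assert peak_shift(shifted, spec) == pytest.approx(delta, abs=0.2)

    def test_edge_maximum_flagged(self):
        ramp = Spectrum(GRID, GRID / 800.0)
        with pytest.raises(ValueError, match="edge"):
            peak_wavelength(ramp, (400.0, 700.0))

    def test_dorsal_shift_smaller_than_ventral_at_equal_x(self, dorsal_model, ventral_model):
        x = 0.5
        shifts = {}
        for name, model, law in (("dorsal", dorsal_model, DORSAL_ETHANOL_LAW),
                                 ("ventral", ventral_model, VENTRAL_ETHANOL_LAW)):
            state = law.state_at(x)
            shifts[name] = peak_shift(model.whole_wing(state), model.zero_vapor)
        assert shifts["dorsal"] < shifts["ventral"]

    def test_peak_shift_linear_in_concentration(self, dorsal_model):
        xs = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        shifts = np.array([
            peak_shift(dorsal_model.whole_wing(DORSAL_ETHANOL_LAW.state_at(x)),
                       dorsal_model.zero_vapor)
            for x in xs
        ])
        slope, intercept = np.polyfit(xs, shifts, 1)
        pred = slope * xs + intercept
        ss_res = np.sum((shifts - pred) ** 2)
        ss_tot = np.sum((shifts - shifts.mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.99
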