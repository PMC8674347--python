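"""Preprocessing chain: grid refit, baseline, smoothing, SD scaling."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ramanmp as rm
from ramanmp.synth import PEAK_TABLES, band_profile


@pytest.fixture
def grid(params):
    return params.grid


class TestRefitGrid:
    def test_default_grid_length_478(self, params):
        assert len(params.grid) == 478

    def test_identity_at_knots(self, params, grid):
        rng = np.random.default_rng(0)
        y = rng.uniform(10, 100, grid.size)
        out = rm.refit_grid(rm.Spectrum(grid, y), params)
        assert np.allclose(out.intensities, y, rtol=1e-9, atol=0)

    def test_linear_function_on_irregular_axis(self, params):
        rng = np.random.default_rng(1)
        axis = np.sort(rng.uniform(540, 2010, 700))
        axis[0], axis[-1] = 540.0, 2010.0
        a, b = 3.0, 0.02
        out = rm.refit_grid(rm.Spectrum(axis, a + b * axis), params)
        expected = a + b * out.wavenumbers
        assert np.allclose(out.intensities, expected, rtol=1e-6)

    def test_no_extrapolation(self, params):
        axis = np.linspace(600, 2000, 100)  # starts above 559
        with pytest.raises(rm.CoverageError):
            rm.refit_grid(rm.Spectrum(axis, np.ones(100)), params)

    @pytest.mark.parametrize(
        "kw",
        [
            {"grid_start": 1000, "grid_end": 900},
            {"grid_step": -1},
            {"grid_start": 559, "grid_end": 1990, "grid_step": 7},
        ],
    )
    def test_invalid_grid_params(self, kw):
        with pytest.raises(ValueError):
            rm.PreprocessParams(**kw)


class TestBaseline:
    def test_pure_constant_offset_removed(self, params, grid):
        offset = 500.0
        out = rm.correct_baseline(rm.Spectrum(grid, np.full(grid.size, offset)), params)
        assert np.mean(np.abs(out.intensities)) < 0.01 * offset

    def test_gaussian_peak_on_quadratic_background(self, params, grid):
        height = 80.0
        peak = height * np.exp(-0.5 * ((grid - 1150) / 9) ** 2)
        t = (grid - grid[0]) / (grid[-1] - grid[0])
        background = 40 + 30 * t + 20 * t**2
        out = rm.correct_baseline(rm.Spectrum(grid, peak + background), params)
        recovered = out.intensities[np.argmax(peak)]
        assert abs(recovered - height) / height < 0.05

    def test_all_zero_in_all_zero_out(self, params, grid):
        out = rm.correct_baseline(rm.Spectrum(grid, np.zeros(grid.size)), params)
        assert np.allclose(out.intensities, 0, atol=1e-12)

    def test_offset_invariance(self, params, grid):
        """Correcting (spectrum + c) matches correcting the spectrum to ≪ c."""
        peak = 60 * np.exp(-0.5 * ((grid - 1000) / 10) ** 2)
        c = 300.0
        a = rm.correct_baseline(rm.Spectrum(grid, peak), params).intensities
        b = rm.correct_baseline(rm.Spectrum(grid, peak + c), params).intensities
        assert np.max(np.abs(a - b)) < 0.01 * c

    def test_baseline_kept_for_audit(self, params, grid):
        y = np.full(grid.size, 10.0)
        out = rm.correct_baseline(rm.Spectrum(grid, y), params)
        assert np.allclose(out.meta["baseline"] + out.intensities, y, atol=1e-9)


class TestSmooth:
    def test_noiseless_signal_preserved(self, params, grid):
        y = 20 + 10 * np.sin(grid / 120)
        out = rm.smooth(rm.Spectrum(grid, y), params)
        assert np.all(np.abs(out.intensities - y) / np.abs(y) < 0.01)

    def test_noise_variance_strictly_reduced(self, params, grid):
        rng = np.random.default_rng(42)
        truth = 20 + 10 * np.sin(grid / 120)
        noise = rng.normal(0, 1.5, grid.size)
        out = rm.smooth(rm.Spectrum(grid, truth + noise), params)
        assert np.var(out.intensities - truth) < np.var(noise)

    def test_constant_unchanged(self, params, grid):
        y = np.full(grid.size, 7.0)
        out = rm.smooth(rm.Spectrum(grid, y), params)
        assert np.allclose(out.intensities, y, rtol=1e-9)


class TestScaleSD:
    def test_unit_sd(self, grid):
        rng = np.random.default_rng(5)
        out = rm.scale_sd(rm.Spectrum(grid, rng.normal(50, 20, grid.size)))
        assert abs(np.std(out.intensities) - 1.0) < 1e-12

    def test_idempotent_and_scale_invariant(self, grid):
        rng = np.random.default_rng(6)
        y = rng.normal(0, 3, grid.size)
        once = rm.scale_sd(rm.Spectrum(grid, y)).intensities
        twice = rm.scale_sd(rm.scale_sd(rm.Spectrum(grid, y))).intensities
        tenfold = rm.scale_sd(rm.Spectrum(grid, 10 * y)).intensities
        assert np.allclose(once, twice, rtol=1e-12)
        assert np.allclose(once, tenfold, rtol=1e-12)

    def test_constant_spectrum_flagged_degenerate(self, grid):
        out = rm.scale_sd(rm.Spectrum(grid, np.full(grid.size, 123.0)))
        assert out.degenerate
        assert np.all(out.intensities == 0)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        scale=st.floats(min_value=1e-3, max_value=1e6),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    def test_scale_invariance_property(self, scale, seed):
        rng = np.random.default_rng(seed)
        axis = np.linspace(550, 2000, 64)
        y = rng.normal(0, 1, 64)
        a = rm.scale_sd(rm.Spectrum(axis, y)).intensities
        b = rm.scale_sd(rm.Spectrum(axis, scale * y)).intensities
        assert np.allclose(a, b, rtol=1e-9, atol=1e-9)


class TestPipeline:
    def test_output_length_478(self, params):
        s = rm.generate_spectrum("PP", snr=30, baseline_coeffs=(1.0, 0.5), seed=0)
        out = rm.preprocess_pipeline(s, params)
        assert len(out) == 478
        assert abs(np.std(out.intensities) - 1.0) < 1e-9

    def test_common_axis_bit_identical(self, params):
        a = rm.preprocess_pipeline(rm.generate_spectrum("PE", seed=1), params)
        b = rm.preprocess_pipeline(rm.generate_spectrum("PS", seed=2), params)
        assert np.array_equal(a.wavenumbers, b.wavenumbers)

    def test_degenerate_constant_input_propagates(self, params):
        axis = np.linspace(540, 2010, 500)
        out = rm.preprocess_pipeline(rm.Spectrum(axis, np.full(500, 88.0)), params)
        assert out.degenerate

    def test_pe_band_positions_survive_preprocessing(self, params):
        """At high SNR the strongest PE bands stay within one grid step of
        where the generator placed them."""
        s = rm.generate_spectrum("PE", snr=200, baseline_coeffs=(2.0, 1.0), seed=3)
        out = rm.preprocess_pipeline(s, params)
        grid = out.wavenumbers
        pure = band_profile(grid, PEAK_TABLES["PE"])
        top = sorted(PEAK_TABLES["PE"], key=lambda b: -b[2])[:3]
        for center, width, _ in top:
            window = (grid > center - 15) & (grid < center + 15)
            got = grid[window][np.argmax(out.intensities[window])]
            want = grid[window][np.argmax(pure[window])]
            assert abs(got - want) <= params.grid_step
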