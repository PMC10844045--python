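"""Spectral evaluation: background, averaging, interpolation, filters, peaks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import flimsort as fs
from flimsort.errors import DomainError, ValidationError


def make_spectrum(intensity, wl=None):
    intensity = np.asarray(intensity, dtype=float)
    if wl is None:
        wl = np.arange(200.0, 200.0 + intensity.size)
    return fs.Spectrum(wavelength_nm=wl, intensity=intensity)


def gaussian_band(wl, center, width, amp=1.0):
    return amp * np.exp(-0.5 * ((wl - center) / width) ** 2)


GRID = np.arange(200.0, 1001.0)


class TestBackgroundAndAveraging:
    def test_identical_background_zeroes_spectrum(self):
        s = make_spectrum(np.linspace(1, 2, 50))
        out = fs.subtract_background(s, s)
        assert np.all(out.intensity == 0)

    def test_negative_differences_clamped(self):
        s = make_spectrum([1.0, 1.0, 1.0])
        bg = make_spectrum([0.5, 2.0, 0.5])
        out = fs.subtract_background(s, bg)
        np.testing.assert_allclose(out.intensity, [0.5, 0.0, 0.5])

    def test_offset_background_recovers_pure_peak(self):
        peak = gaussian_band(GRID, 563.0, 9.0)
        sample = make_spectrum(peak + 0.3, wl=GRID)
        out = fs.subtract_background(sample, make_spectrum(np.full(GRID.size, 0.3), wl=GRID))
        np.testing.assert_allclose(out.intensity, peak, atol=1e-12)

    def test_grid_mismatch(self):
        with pytest.raises(ValidationError):
            fs.subtract_background(make_spectrum([1, 2]), make_spectrum([1, 2, 3]))

    def test_average_identical_replicates(self):
        s = make_spectrum(np.linspace(0, 1, 30))
        out = fs.average_spectra([s] * 5)
        np.testing.assert_allclose(out.intensity, s.intensity)

    def test_average_two_constant_spectra(self):
        out = fs.average_spectra([make_spectrum(np.zeros(10)), make_spectrum(np.ones(10))])
        assert np.all(out.intensity == 0.5)

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            fs.average_spectra([])

    def test_averaging_reduces_noise_variance_fivefold(self, rng):
        """Mean of 5 replicates: peak stays put, noise variance drops ~x5."""
        truth = gaussian_band(GRID, 563.0, 9.0, amp=10.0)
        reps = [
            make_spectrum(truth + rng.normal(0, 0.5, GRID.size), wl=GRID) for _ in range(5)
        ]
        mean = fs.average_spectra(reps)
        residual_var = np.var(mean.intensity - truth)
        single_var = np.var(reps[0].intensity - truth)
        assert residual_var == pytest.approx(single_var / 5, rel=0.25)
        assert abs(GRID[np.argmax(mean.intensity)] - 563.0) <= 1.0


class TestInterpolation:
    def test_linear_ramp_preserved(self):
        s = make_spectrum(np.arange(10.0), wl=np.arange(500.0, 510.0))
        fine = fs.interpolate_spectrum(s, step_nm=0.01)
        np.testing.assert_allclose(fine.intensity, fine.wavelength_nm - 500.0, atol=1e-9)

    def test_endpoints_and_samples_exact(self):
        s = make_spectrum([1.0, 5.0, 2.0], wl=np.array([500.0, 501.0, 502.0]))
        fine = fs.interpolate_spectrum(s, step_nm=0.01)
        assert fine.wavelength_nm[0] == 500.0 and fine.wavelength_nm[-1] == 502.0
        for wl, it in zip(s.wavelength_nm, s.intensity):
            assert fine.intensity[np.argmin(np.abs(fine.wavelength_nm - wl))] == pytest.approx(it)

    def test_triangular_peak_located_to_hundredth_nm(self):
        # triangular peak with apex at 528 nm on a 1 nm grid
        s = make_spectrum(np.maximum(0, 10 - np.abs(GRID - 528.0)), wl=GRID)
        fine = fs.interpolate_spectrum(s, step_nm=0.01)
        apex = fine.wavelength_nm[np.argmax(fine.intensity)]
        assert apex == pytest.approx(528.0, abs=0.01)

    def test_bad_step(self):
        with pytest.raises(DomainError):
            fs.interpolate_spectrum(make_spectrum([1, 2]), step_nm=0.0)


class TestFilters:
    def test_bp_blocks_chlorophyll_band(self):
        """A 700 nm emitter is entirely blocked by the 495-550 nm band-pass."""
        s = make_spectrum(gaussian_band(GRID, 700.0, 8.0), wl=GRID)
        out = fs.apply_filter(s, fs.BP495_550)
        assert np.all(out.intensity[np.abs(out.intensity) > 1e-12] == 0)

    def test_lp_identity_above_cuton(self):
        wl = np.arange(520.0, 600.0)
        s = make_spectrum(np.random.default_rng(0).uniform(0, 1, wl.size), wl=wl)
        out = fs.apply_filter(s, fs.LP500)
        np.testing.assert_array_equal(out.intensity, s.intensity)

    def test_bp_keeps_only_polymer_peak_of_hdpe(self):
        """Of the HDPE doublet (528/594 nm) only the 528 nm band survives the BP."""
        s = make_spectrum(
            gaussian_band(GRID, 528.0, 8.0) + 0.8 * gaussian_band(GRID, 594.0, 10.0), wl=GRID
        )
        peaks = fs.find_peaks(fs.apply_filter(s, fs.BP495_550))
        assert [round(p.wavelength_nm) for p in peaks] == [528]

    def test_bp_filter_invariants(self):
        with pytest.raises(ValidationError):
            fs.OpticalFilter("BP", 550.0, 495.0)
        with pytest.raises(ValidationError):
            fs.OpticalFilter("XX", 500.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_filter_never_increases_intensity(self, seed):
        r = np.random.default_rng(seed)
        s = make_spectrum(r.uniform(0, 5, GRID.size), wl=GRID)
        for f in (fs.LP500, fs.BP495_550):
            assert np.all(fs.apply_filter(s, f).intensity <= s.intensity + 1e-12)

    def test_bp_peaks_subset_of_unfiltered_passband_peaks(self):
        s = make_spectrum(
            gaussian_band(GRID, 528.0, 8.0)
            + 0.8 * gaussian_band(GRID, 594.0, 10.0)
            + 0.6 * gaussian_band(GRID, 510.0, 5.0),
            wl=GRID,
        )
        unfiltered = {p.wavelength_nm for p in fs.find_peaks(s)}
        filtered = fs.find_peaks(fs.apply_filter(s, fs.BP495_550))
        assert {p.wavelength_nm for p in filtered} <= unfiltered


class TestPeaksAndStokes:
    def test_single_spruce_peak(self):
        s = make_spectrum(gaussian_band(GRID, 563.0, 9.0), wl=GRID)
        peaks = fs.find_peaks(s)
        assert len(peaks) == 1
        assert peaks[0].wavelength_nm == pytest.approx(563.0)
        assert peaks[0].stokes_shift_nm == pytest.approx(75.0)

    def test_flat_spectrum_has_no_peaks(self):
        assert fs.find_peaks(make_spectrum(np.ones(100))) == []
        assert fs.find_peaks(make_spectrum(np.zeros(100))) == []

    def test_grass_triplet_resolved(self):
        s = fs.render_spectrum(fs.MATERIAL_LIBRARY["grass"], grid=GRID)
        peaks = fs.find_peaks(s)
        assert [round(p.wavelength_nm) for p in peaks] == [691, 719, 741]
        assert [round(p.stokes_shift_nm) for p in peaks] == [203, 231, 253]

    @pytest.mark.parametrize(
        "peak_nm, shift", [(528, 40), (594, 106), (488, 0), (563, 75), (539, 51)]
    )
    def test_stokes_shift_values(self, peak_nm, shift):
        assert fs.stokes_shift(peak_nm) == shift

    def test_anti_stokes_rejected(self):
        with pytest.raises(DomainError):
            fs.stokes_shift(450.0)


class TestNormalize:
    def test_peak_becomes_one_and_idempotent(self):
        s = make_spectrum(gaussian_band(GRID, 563.0, 9.0, amp=5.0), wl=GRID)
        n1 = fs.normalize_spectrum(s)
        assert np.max(n1.intensity) == 1.0
        n2 = fs.normalize_spectrum(n1)
        np.testing.assert_array_equal(n1.intensity, n2.intensity)

    def test_all_zero_rejected(self):
        with pytest.raises(DomainError):
            fs.normalize_spectrum(make_spectrum(np.zeros(10)))
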