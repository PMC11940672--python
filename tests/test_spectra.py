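"""Spectral-core operators: masking, integration, exposure normalization,
peak refinement and the scattering-corrected fluorescence index."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phycowatch import (
    Band,
    MeasurementPair,
    Spectrum,
    band_integral,
    default_grid,
    find_peak,
    fluorescence_index,
    mask_saturated,
    normalize_exposure,
)
from phycowatch.errors import (
    BandRangeError,
    InsufficientDataError,
    NormalizationError,
    SaturationError,
)

from conftest import flat_spectrum


def make_spectrum(wl, intensities, exposure_s=1.0, saturation=65535.0):
    return Spectrum(
        wavelengths_nm=np.asarray(wl, float),
        intensities=np.asarray(intensities, float),
        exposure_s=exposure_s,
        saturation_counts=saturation,
    )


class TestSpectrumInvariants:
    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError):
            make_spectrum([650, 651], [1.0])

    def test_rejects_non_monotone_grid(self):
        with pytest.raises(ValueError):
            make_spectrum([650, 650, 651], [1, 2, 3])

    def test_rejects_nonpositive_exposure(self):
        with pytest.raises(ValueError):
            make_spectrum([650, 651], [1, 2], exposure_s=0.0)

    def test_rejects_counts_above_full_scale(self):
        with pytest.raises(ValueError):
            make_spectrum([650, 651], [1, 70000])

    def test_default_grid_matches_detector(self):
        grid = default_grid()
        assert grid[0] == 225.0 and grid[-1] <= 1000.0
        assert np.allclose(np.diff(grid), 1.5)


class TestMaskSaturated:
    @pytest.mark.parametrize(
        "intensities,threshold,expected",
        [
            ([10, 65535, 65535, 40], 1.0, [False, True, True, False]),
            ([0, 0, 0], 0.5, [False, False, False]),
            # 0.9 x 65535 = 58981.5
            ([100, 59000, 65000], 0.9, [False, True, True]),
        ],
    )
    def test_threshold_comparison(self, intensities, threshold, expected):
        sp = make_spectrum(650 + np.arange(len(intensities)), intensities)
        assert mask_saturated(sp, threshold).tolist() == expected

    def test_input_unmodified_and_bad_threshold(self):
        sp = make_spectrum([650, 651], [10, 65535])
        before = sp.intensities.copy()
        mask_saturated(sp)
        assert np.array_equal(sp.intensities, before)
        with pytest.raises(ValueError):
            mask_saturated(sp, 0.0)


class TestBandIntegral:
    def test_trapezoid_against_hand_computation(self):
        sp = make_spectrum([650, 651, 652], [10, 20, 10])
        # (10+20)/2 + (20+10)/2 = 30
        assert band_integral(sp, Band(650, 652)) == pytest.approx(30.0)

    def test_all_zero_and_single_sample(self):
        sp = make_spectrum([650, 651, 652], [0, 0, 0])
        assert band_integral(sp, Band(650, 652)) == 0.0
        sp2 = make_spectrum([650, 651, 652], [5, 7, 9])
        mask = np.array([True, False, True])
        assert band_integral(sp2, Band(650, 652), mask) == 0.0

    def test_band_outside_range_raises(self):
        sp = make_spectrum([650, 651, 652], [1, 2, 3])
        with pytest.raises(BandRangeError):
            band_integral(sp, Band(600, 660))

    def test_matches_dense_grid_oracle_for_gaussian(self):
        """1.5 nm trapezoid within 2% of a 0.01 nm reference integral."""
        sigma = 25.0 / 2.3548
        band = Band(640.0, 680.0)
        coarse = default_grid()
        dense = np.arange(640.0, 680.0 + 1e-9, 0.01)

        def gauss(x):
            return 1000.0 * np.exp(-0.5 * ((x - 657.0) / sigma) ** 2)

        sp = make_spectrum(coarse, gauss(coarse))
        oracle = np.trapezoid(gauss(dense), dense)
        assert band_integral(sp, band) == pytest.approx(oracle, rel=0.02)


class TestNormalizeExposure:
    def test_linear_scaling_and_identity(self):
        sp = flat_spectrum(650, 660, 1.0, 50.0, exposure_s=0.1)
        up = normalize_exposure(sp, 1.0)
        assert np.allclose(up.intensities, 500.0)
        assert up.exposure_s == 1.0
        same = normalize_exposure(sp, 0.1)
        assert np.allclose(same.intensities, sp.intensities)

    def test_downscaling_arithmetic(self):
        sp = flat_spectrum(650, 660, 1.0, 200.0, exposure_s=5.0)
        down = normalize_exposure(sp, 0.1)
        assert np.allclose(down.intensities, 4.0)

    def test_saturated_samples_flagged_not_rescaled(self):
        sp = make_spectrum([650, 651, 652], [100, 65535, 200], exposure_s=1.0)
        out = normalize_exposure(sp, 2.0)
        assert out.intensities[1] == 65535.0  # carried, not doubled
        assert out.saturated.tolist() == [False, True, False]
        assert np.allclose(out.intensities[[0, 2]], [200, 400])

    def test_rejects_nonpositive_target(self):
        sp = flat_spectrum(650, 660, 1.0, 50.0, exposure_s=0.1)
        with pytest.raises(ValueError):
            normalize_exposure(sp, 0.0)

    @given(
        exposure=st.floats(0.01, 10.0),
        target=st.floats(0.01, 10.0),
        amplitude=st.floats(1.0, 1000.0),
        center=st.floats(400.0, 800.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_exposure_linearity_property(self, exposure, target, amplitude, center):
        """Rescaling a noiseless sub-saturation spectrum reproduces the
        spectrum acquired at the target exposure, to 1e-9 relative."""
        wl = default_grid()
        shape = amplitude * np.exp(-0.5 * ((wl - center) / 12.0) ** 2)
        s1 = make_spectrum(wl, shape * exposure, exposure_s=exposure)
        s2 = make_spectrum(wl, shape * target, exposure_s=target)
        out = normalize_exposure(s1, target)
        np.testing.assert_allclose(out.intensities, s2.intensities,
                                   rtol=1e-9, atol=1e-12)


class TestFindPeak:
    def test_gaussian_center_recovered_on_default_grid(self):
        """Parabolic refinement of a sampled Gaussian, checked against a
        dense-grid argmax oracle."""
        wl = default_grid()
        sigma = 25.0 / 2.3548
        for center in (657.0, 656.3, 657.8):
            sp = make_spectrum(wl, 5000 * np.exp(-0.5 * ((wl - center) / sigma) ** 2))
            dense = np.arange(630, 700, 0.001)
            oracle = dense[np.argmax(np.exp(-0.5 * ((dense - center) / sigma) ** 2))]
            peak_nm, height = find_peak(sp, Band(630, 700))
            assert peak_nm == pytest.approx(oracle, abs=0.2)
            assert height > 0

    def test_monotone_ramp_returns_band_edge(self):
        wl = np.arange(650.0, 661.0)
        sp = make_spectrum(wl, np.arange(11.0))
        peak_nm, height = find_peak(sp, Band(650, 660))
        assert (peak_nm, height) == (660.0, 10.0)

    def test_tie_breaks_to_shorter_wavelength(self):
        wl = np.arange(645.0, 666.0)
        y = np.zeros_like(wl)
        y[wl == 650.0] = 10.0
        y[wl == 660.0] = 10.0
        peak_nm, _ = find_peak(make_spectrum(wl, y), Band(645, 665))
        assert peak_nm == pytest.approx(650.0, abs=1e-9)

    def test_too_few_usable_samples(self):
        sp = make_spectrum([650, 651, 652, 653], [1, 2, 3, 1])
        with pytest.raises(InsufficientDataError):
            find_peak(sp, Band(650, 653), np.array([True, True, False, False]))


class TestFluorescenceIndex:
    def _pair(self, short_value, long_value, gain=1.0):
        short = flat_spectrum(560, 700, 1.0, short_value * gain, 0.1, led_id="615nm")
        long = flat_spectrum(560, 700, 1.0, long_value * gain, 5.0, led_id="615nm")
        return MeasurementPair(led_id="615nm", short=short, long=long)

    def test_rate_ratio_arithmetic(self):
        """Fluor 500 counts·nm @ 5 s over LED 1000 counts·nm @ 0.1 s
        gives (500/5)/(1000/0.1) = 0.01."""
        pair = self._pair(short_value=100.0, long_value=50.0)
        idx = fluorescence_index(pair, Band(650, 660), Band(610, 620))
        assert idx == pytest.approx(0.01)

    def test_zero_fluorescence_gives_zero(self):
        pair = self._pair(short_value=100.0, long_value=0.0)
        assert fluorescence_index(pair, Band(650, 660), Band(610, 620)) == 0.0

    def test_zero_led_reference_raises(self):
        pair = self._pair(short_value=0.0, long_value=50.0)
        with pytest.raises(NormalizationError):
            fluorescence_index(pair, Band(650, 660), Band(610, 620))

    def test_fully_saturated_fluor_band_raises(self):
        short = flat_spectrum(560, 700, 1.0, 100.0, 0.1, led_id="615nm")
        long = flat_spectrum(560, 700, 1.0, 65535.0, 5.0, led_id="615nm")
        pair = MeasurementPair(led_id="615nm", short=short, long=long)
        with pytest.raises(SaturationError):
            fluorescence_index(pair, Band(650, 660), Band(610, 620))

    @given(gain=st.floats(1e-3, 500.0))
    @settings(max_examples=50, deadline=None)
    def test_gain_invariance_property(self, gain):
        base = fluorescence_index(
            self._pair(100.0, 50.0), Band(650, 660), Band(610, 620)
        )
        scaled = fluorescence_index(
            self._pair(100.0, 50.0, gain=gain), Band(650, 660), Band(610, 620)
        )
        assert scaled == pytest.approx(base, rel=1e-12)

    def test_height_mode_also_gain_invariant(self, noiseless_pair):
        a = fluorescence_index(noiseless_pair, Band(640, 680), Band(605, 625),
                               mode="height")
        assert a > 0
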