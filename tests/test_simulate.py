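"""Virtual-reactor forward model and culture dynamics."""

import numpy as np
import pytest

from phycowatch import (
    Band,
    CultureState,
    FluorophoreSpec,
    LedChannel,
    MeasurementPair,
    OpticalModel,
    ScenarioConfig,
    Spectrum,
    band_integral,
    excitation_efficiency,
    expected_spectrum,
    fluorescence_index,
    generate_calibration_series,
    get_led,
    led_bank,
    led_emission,
    read_od,
    simulate_spectrum,
    step_culture,
)
from phycowatch.errors import ConfigError
from phycowatch.library import FLUOROPHORES
from phycowatch.spectra import default_grid

from conftest import PC_FLUOR_BAND, PC_LED_BAND


class TestLedEmission:
    def test_profile_peaks_at_channel_wavelength(self):
        grid = default_grid()
        ch = get_led("615nm")
        profile = led_emission(ch, grid)
        nearest = grid[np.argmin(np.abs(grid - 615.0))]
        assert grid[np.argmax(profile)] == nearest

    def test_disabled_channel_emits_nothing(self):
        ch = LedChannel(led_id="x", peak_nm=500, fwhm_nm=20,
                        radiant_power_mw=100, enabled=False)
        assert not led_emission(ch, default_grid()).any()

    def test_half_maximum_at_half_width(self):
        ch = LedChannel(led_id="x", peak_nm=600, fwhm_nm=20, radiant_power_mw=50)
        grid = np.array([590.0, 600.0, 610.0])
        prof = led_emission(ch, grid)
        assert prof[0] == pytest.approx(prof[1] / 2, rel=0.01)
        assert prof[2] == pytest.approx(prof[1] / 2, rel=0.01)

    def test_integral_proportional_to_radiant_power(self):
        grid = default_grid()
        lo = LedChannel(led_id="a", peak_nm=600, fwhm_nm=20, radiant_power_mw=100)
        hi = LedChannel(led_id="b", peak_nm=600, fwhm_nm=20, radiant_power_mw=300)
        ratio = np.trapezoid(led_emission(hi, grid), grid) / np.trapezoid(
            led_emission(lo, grid), grid
        )
        assert ratio == pytest.approx(3.0, rel=1e-6)


class TestExcitationEfficiency:
    def test_maximal_when_led_matches_excitation_maximum(self):
        fluor = FLUOROPHORES["rhodamine_6g"]  # single 525 nm band
        effs = {
            peak: excitation_efficiency(
                fluor,
                LedChannel(led_id="x", peak_nm=peak, fwhm_nm=30.0,
                           radiant_power_mw=100),
            )
            for peak in np.arange(400, 700, 5.0)
        }
        assert max(effs, key=effs.get) == 525.0

    def test_monotone_decay_with_detuning(self):
        fluor = FLUOROPHORES["phycocyanin"]
        deltas = [0, 10, 25, 50, 100]
        effs = [
            excitation_efficiency(
                fluor,
                LedChannel(led_id="x", peak_nm=620.0 + d, fwhm_nm=20.0,
                           radiant_power_mw=100),
            )
            for d in deltas
        ]
        assert all(a > b for a, b in zip(effs, effs[1:]))

    def test_far_detuned_led_is_dark(self):
        fluor = FluorophoreSpec(
            name="x", excitation_max_nm=(500.0,), excitation_width_nm=20.0,
            emission_max_nm=550.0, emission_width_nm=20.0, brightness=1.0,
        )
        ch = LedChannel(led_id="x", peak_nm=700.0, fwhm_nm=20.0,
                        radiant_power_mw=100)
        assert excitation_efficiency(fluor, ch) < 1e-6

    def test_phycocyanin_prefers_615_over_373(self):
        pc = FLUOROPHORES["phycocyanin"]
        assert excitation_efficiency(pc, get_led("615nm")) > excitation_efficiency(
            pc, get_led("373nm")
        )


class TestSimulateSpectrum:
    def test_empty_vial_is_dark(self):
        optics = OpticalModel(medium_scatter_equiv=0.0)
        state = CultureState(biomass_cells_per_ul=0.0)
        sp = simulate_spectrum(state, get_led("615nm"), 1.0, optics, rng=None)
        assert not sp.intensities.any()

    def test_exposure_linearity_by_construction(self, optics):
        state = CultureState(biomass_cells_per_ul=100.0)
        ch = get_led("615nm")
        s1 = expected_spectrum(state, ch, 0.1, optics)
        s2 = expected_spectrum(state, ch, 5.0, optics)
        np.testing.assert_allclose(s2, 50.0 * s1, rtol=1e-12)

    def test_led_band_integral_doubles_with_biomass(self):
        """Pure-culture scattering is linear in particle density (no
        medium floor), so doubling biomass doubles the excitation-line
        integral."""
        optics = OpticalModel(medium_scatter_equiv=0.0)
        ch = get_led("615nm")

        def led_int(biomass):
            st = CultureState(biomass_cells_per_ul=biomass,
                              pigment_per_cell={"phycocyanin": 1.0})
            sp = simulate_spectrum(st, ch, 0.1, optics, rng=None)
            return band_integral(sp, PC_LED_BAND)

        assert led_int(400.0) == pytest.approx(2 * led_int(200.0), rel=1e-9)

    def test_scattering_monotone_in_particle_density(self, optics):
        ch = get_led("615nm")
        integrals = []
        for total in [0, 100, 300, 900]:
            st = CultureState(biomass_cells_per_ul=total / 2,
                              contaminant_cells_per_ul=total / 2)
            sp = simulate_spectrum(st, ch, 0.1, optics, rng=None)
            integrals.append(band_integral(sp, PC_LED_BAND))
        assert all(a < b for a, b in zip(integrals, integrals[1:]))

    def test_long_exposure_saturates_excitation_line(self, optics):
        """The fluorescence capture clips the directly scattered LED line at
        full scale while the short capture keeps it quantifiable."""
        st = CultureState(biomass_cells_per_ul=500.0)
        ch = get_led("615nm")
        short = simulate_spectrum(st, ch, 0.1, optics, rng=None)
        long = simulate_spectrum(st, ch, 5.0, optics, rng=None)
        in_led = (short.wavelengths_nm >= 605) & (short.wavelengths_nm <= 625)
        assert not short.saturated[in_led].any()
        assert long.saturated[in_led].any()

    def test_noise_is_reproducible_by_seed(self, optics):
        st = CultureState(biomass_cells_per_ul=200.0)
        ch = get_led("615nm")
        a = simulate_spectrum(st, ch, 1.0, optics, np.random.default_rng(42))
        b = simulate_spectrum(st, ch, 1.0, optics, np.random.default_rng(42))
        np.testing.assert_array_equal(a.intensities, b.intensities)


class TestStepCulture:
    def test_growth_matches_exponential_phase(self):
        cfg = ScenarioConfig.growth()
        state = CultureState(biomass_cells_per_ul=10.0)  # far below capacity
        dt = 1.0  # r*dt = 0.04
        out = step_culture(state, cfg, dt)
        expected = 10.0 * (1 + cfg.growth_rate_per_h * dt)
        assert out.biomass_cells_per_ul == pytest.approx(expected, rel=0.05)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ConfigError):
            ScenarioConfig(scenario="mystery")

    def test_densities_stay_nonnegative(self):
        cfg = ScenarioConfig.photoinhibition(death_rate_per_h=5.0,
                                             viability_fraction=1.1)
        state = cfg.initial_state()
        for _ in range(200):
            state = step_culture(state, cfg, 0.5)
            assert state.biomass_cells_per_ul >= 0
            assert all(v >= 0 for v in state.pigment_per_cell.values())

    def test_photoinhibition_pulse_then_monotone_decay(self):
        """Noise-free phycocyanin trace on a dense time grid: transient
        rise peaking between 0 and 5 h, monotone decline afterwards."""
        cfg = ScenarioConfig.photoinhibition()
        state = cfg.initial_state()
        trace = []
        for _ in range(241):  # 24 h at 0.1 h
            trace.append(
                state.biomass_cells_per_ul
                * state.pigment_per_cell["phycocyanin"]
                * state.yield_modifier
            )
            state = step_culture(state, cfg, 0.1)
        trace = np.array(trace)
        imax = int(trace.argmax())
        assert 0 < imax * 0.1 < 5.0
        assert np.all(np.diff(trace[imax:]) <= 1e-9)

    def test_contamination_od_up_fluorescence_down(self):
        cfg = ScenarioConfig.contamination()
        state = cfg.initial_state()
        od, fluor = [], []
        for _ in range(240):
            od.append(read_od(state))
            fluor.append(
                state.biomass_cells_per_ul
                * state.pigment_per_cell["phycocyanin"]
                * state.yield_modifier
            )
            state = step_culture(state, cfg, 0.1)
        assert od[-1] > od[0] * 1.2
        assert all(a >= b - 1e-12 for a, b in zip(fluor, fluor[1:]))


class TestReadOd:
    def test_empty_vial_baseline_zero(self):
        assert read_od(CultureState(biomass_cells_per_ul=0.0)) == 0.0

    def test_linear_in_density(self):
        a = read_od(CultureState(biomass_cells_per_ul=100.0))
        b = read_od(CultureState(biomass_cells_per_ul=200.0))
        assert b == pytest.approx(2 * a)

    def test_blind_to_scatterer_identity(self):
        mixed = CultureState(biomass_cells_per_ul=100.0,
                             contaminant_cells_per_ul=50.0)
        pure = CultureState(biomass_cells_per_ul=150.0)
        assert read_od(mixed) == pytest.approx(read_od(pure))


class TestCalibrationSeries:
    def test_noiseless_index_monotone_in_concentration(self):
        optics = OpticalModel(read_noise_sigma=0.0, shot_noise=False)
        cal, _ = generate_calibration_series(
            [0, 50, 150, 300, 500], 3, optics=optics, rng=None
        )
        idx = cal["index"].to_numpy()
        assert np.all(np.diff(idx) > 0)

    def test_zero_concentrations_match_blanks(self, optics):
        rng = np.random.default_rng(11)
        cal, blanks = generate_calibration_series(
            [0.0] * 10, 10, optics=optics, rng=rng
        )
        idx = cal["index"].to_numpy()
        pooled_se = np.sqrt(idx.var(ddof=1) / len(idx) +
                            blanks.var(ddof=1) / len(blanks))
        assert abs(idx.mean() - blanks.mean()) < 3 * pooled_se

    def test_blank_means_agree_across_seeds(self, optics):
        means, ses = [], []
        for seed in (101, 202):
            _, blanks = generate_calibration_series(
                [0.0], 30, optics=optics, rng=np.random.default_rng(seed)
            )
            means.append(blanks.mean())
            ses.append(blanks.var(ddof=1) / len(blanks))
        assert abs(means[0] - means[1]) < 3 * np.sqrt(ses[0] + ses[1])
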