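import numpy as np
import pytest

from phycowatch import (
    Band,
    CultureState,
    MeasurementPair,
    OpticalModel,
    Spectrum,
    get_led,
    simulate_spectrum,
)

PC_FLUOR_BAND = Band(640.0, 680.0)
PC_LED_BAND = Band(605.0, 625.0)


@pytest.fixture
def optics():
    return OpticalModel()


@pytest.fixture
def noiseless_pair(optics):
    """Dual-exposure pair from a dense, healthy culture (no noise)."""
    state = CultureState(biomass_cells_per_ul=500.0)
    channel = get_led("615nm")
    short = simulate_spectrum(state, channel, 0.1, optics, rng=None)
    long = simulate_spectrum(state, channel, 5.0, optics, rng=None)
    return MeasurementPair(led_id="615nm", short=short, long=long)


def flat_spectrum(lo, hi, step, value, exposure_s, saturation=65535.0, led_id="none"):
    wl = np.arange(lo, hi + step / 2, step, dtype=float)
    return Spectrum(
        wavelengths_nm=wl,
        intensities=np.full_like(wl, float(value)),
        exposure_s=exposure_s,
        saturation_counts=saturation,
        led_id=led_id,
    )
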