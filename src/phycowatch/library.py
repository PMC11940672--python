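"""Built-in instrument and fluorophore reference data.

The six-channel excitation bank mirrors the high-power LED module of the
physical instrument (measured emission peaks and radiant powers).  The
fluorophore table holds literature excitation/emission maxima for the
substances used to validate the optics, plus the two cyanobacterial pigments
the monitor targets: phycocyanin (the phycobilisome pigment, absorbing at
620–630 nm and emitting near 650–657 nm) and chlorophyll a.

Spectral widths (FWHM) and relative brightnesses are model parameters of the
virtual reactor, not literature constants; see the methods note.
"""

from __future__ import annotations

from .simulate import FluorophoreSpec, LedChannel

#: The six excitation channels: (peak nm, radiant power mW).
DEFAULT_LED_BANK: list[LedChannel] = [
    LedChannel(led_id="657nm", peak_nm=657.0, fwhm_nm=20.0, radiant_power_mw=450.0),
    LedChannel(led_id="615nm", peak_nm=615.0, fwhm_nm=20.0, radiant_power_mw=334.0),
    LedChannel(led_id="586nm", peak_nm=586.0, fwhm_nm=20.0, radiant_power_mw=242.0),
    LedChannel(led_id="520nm", peak_nm=520.0, fwhm_nm=20.0, radiant_power_mw=270.0),
    LedChannel(led_id="451nm", peak_nm=451.0, fwhm_nm=20.0, radiant_power_mw=600.0),
    LedChannel(led_id="373nm", peak_nm=373.0, fwhm_nm=20.0, radiant_power_mw=930.0),
]

FLUOROPHORES: dict[str, FluorophoreSpec] = {
    "quinine": FluorophoreSpec(
        name="quinine",
        excitation_max_nm=(349.0,),
        excitation_width_nm=40.0,
        emission_max_nm=461.0,
        emission_width_nm=60.0,
        brightness=500.0,
    ),
    "rhodamine_6g": FluorophoreSpec(
        name="rhodamine_6g",
        excitation_max_nm=(525.0,),
        excitation_width_nm=30.0,
        emission_max_nm=548.0,
        emission_width_nm=35.0,
        brightness=600.0,
    ),
    "rhodamine_b": FluorophoreSpec(
        name="rhodamine_b",
        excitation_max_nm=(546.0,),
        excitation_width_nm=30.0,
        emission_max_nm=567.0,
        emission_width_nm=35.0,
        brightness=600.0,
    ),
    "phycocyanin": FluorophoreSpec(
        name="phycocyanin",
        excitation_max_nm=(620.0,),
        excitation_width_nm=25.0,
        emission_max_nm=650.0,
        emission_width_nm=25.0,
        brightness=250.0,
    ),
    "chlorophyll_a": FluorophoreSpec(
        name="chlorophyll_a",
        excitation_max_nm=(429.0, 661.0),
        excitation_width_nm=30.0,
        emission_max_nm=673.0,
        emission_width_nm=30.0,
        brightness=120.0,
    ),
}


def led_bank() -> list[LedChannel]:
    """A fresh copy of the default six-channel bank."""
    return [LedChannel(**vars(ch)) for ch in DEFAULT_LED_BANK]


def get_led(led_id: str) -> LedChannel:
    for ch in DEFAULT_LED_BANK:
        if ch.led_id == led_id:
            return LedChannel(**vars(ch))
    raise KeyError(f"unknown LED channel {led_id!r}")
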