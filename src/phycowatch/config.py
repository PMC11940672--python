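"""Run configuration: validated YAML schema with instrument defaults.

A minimal file (even just a scenario name) expands to the full default
configuration: the six-channel excitation bank, the 225–1000 nm / 1.5 nm
virtual spectrometer, the 0.1 s / 5.0 s exposure pair, the phycocyanin
emission window and a 60 min measurement interval.  Unknown keys are
rejected so typos fail loudly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional, Union

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .errors import ConfigError
from .simulate import LedChannel, OpticalModel, ScenarioConfig
from .spectra import Band


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class LedChannelCfg(_Strict):
    led_id: Optional[str] = None
    peak_nm: float = Field(gt=0)
    fwhm_nm: float = Field(default=20.0, gt=0)
    radiant_power_mw: float = Field(ge=0)
    enabled: bool = True

    def to_channel(self) -> LedChannel:
        return LedChannel(
            led_id=self.led_id or f"{self.peak_nm:g}nm",
            peak_nm=self.peak_nm,
            fwhm_nm=self.fwhm_nm,
            radiant_power_mw=self.radiant_power_mw,
            enabled=self.enabled,
        )


def _default_bank_cfg() -> list[LedChannelCfg]:
    from .library import DEFAULT_LED_BANK

    return [
        LedChannelCfg(
            led_id=ch.led_id, peak_nm=ch.peak_nm, fwhm_nm=ch.fwhm_nm,
            radiant_power_mw=ch.radiant_power_mw, enabled=ch.enabled,
        )
        for ch in DEFAULT_LED_BANK
    ]


class SpectrometerCfg(_Strict):
    min_nm: float = 225.0
    max_nm: float = 1000.0
    step_nm: float = Field(default=1.5, gt=0)
    saturation_counts: float = Field(default=65535.0, gt=0)

    @model_validator(mode="after")
    def _range_ok(self) -> "SpectrometerCfg":
        if not self.min_nm < self.max_nm:
            raise ValueError("spectrometer range requires min_nm < max_nm")
        return self

    def grid(self) -> np.ndarray:
        from .spectra import default_grid

        return default_grid(self.min_nm, self.max_nm, self.step_nm)


class BandsCfg(_Strict):
    led_halfwidth_nm: float = Field(default=10.0, gt=0)
    fluor_lo_nm: float = 640.0
    fluor_hi_nm: float = 680.0
    normalization_mode: Literal["area", "height"] = "area"

    @model_validator(mode="after")
    def _band_ok(self) -> "BandsCfg":
        if not self.fluor_lo_nm < self.fluor_hi_nm:
            raise ValueError("fluorescence band requires lo < hi")
        return self

    def fluor_band(self) -> Band:
        return Band(self.fluor_lo_nm, self.fluor_hi_nm)


class ExposuresCfg(_Strict):
    short_s: float = Field(default=0.1, gt=0)
    long_s: float = Field(default=5.0, gt=0)

    @model_validator(mode="after")
    def _order(self) -> "ExposuresCfg":
        if not self.short_s < self.long_s:
            raise ValueError("short_s must be strictly less than long_s")
        return self


class ScenarioCfg(_Strict):
    name: Literal["growth", "photoinhibition", "contamination", "calibration"] = "growth"
    growth_rate_per_h: Optional[float] = None
    carrying_capacity: Optional[float] = None
    irradiance_umol: Optional[float] = None
    critical_irradiance_umol: Optional[float] = None
    pigment_decay_per_h: Optional[float] = None
    yield_pulse_amplitude: Optional[float] = None
    yield_pulse_decay_per_h: Optional[float] = None
    contaminant_growth_rate_per_h: Optional[float] = None
    viability_fraction: Optional[float] = None
    death_rate_per_h: Optional[float] = None
    initial_biomass_cells_per_ul: Optional[float] = None
    initial_contaminant_cells_per_ul: Optional[float] = None
    read_noise_sigma: Optional[float] = None
    shot_noise: Optional[bool] = None

    def to_scenario(self, seed: int) -> ScenarioConfig:
        overrides = {
            k: v for k, v in self.model_dump().items()
            if k != "name" and v is not None
        }
        ctor = getattr(ScenarioConfig, self.name)
        return ctor(seed=seed, **overrides)


class OpticsCfg(_Strict):
    scatter_coeff: float = Field(default=3.0, gt=0)
    medium_scatter_equiv: float = Field(default=5000.0, ge=0)


class RunConfig(_Strict):
    """Top-level run configuration."""

    leds: list[LedChannelCfg] = Field(default_factory=_default_bank_cfg)
    spectrometer: SpectrometerCfg = Field(default_factory=SpectrometerCfg)
    bands: BandsCfg = Field(default_factory=BandsCfg)
    exposures: ExposuresCfg = Field(default_factory=ExposuresCfg)
    interval_min: float = Field(default=60.0, gt=0)
    duration_h: float = Field(default=24.0, gt=0)
    od_cadence_s: float = Field(default=5.0, gt=0)
    scenario: ScenarioCfg = Field(default_factory=ScenarioCfg)
    optics: OpticsCfg = Field(default_factory=OpticsCfg)
    monitor_leds: Optional[list[str]] = None
    out_dir: str = "run"
    seed: int = 1

    @model_validator(mode="after")
    def _leds_in_range(self) -> "RunConfig":
        for led in self.leds:
            if not self.spectrometer.min_nm <= led.peak_nm <= self.spectrometer.max_nm:
                raise ValueError(
                    f"LED peak {led.peak_nm} nm outside detector range"
                )
        return self

    # -- materialization ---------------------------------------------------
    def led_channels(self) -> list[LedChannel]:
        return [cfg.to_channel() for cfg in self.leds]

    def scenario_config(self) -> ScenarioConfig:
        return self.scenario.to_scenario(self.seed)

    def optical_model(self) -> OpticalModel:
        return OpticalModel(
            wavelengths_nm=self.spectrometer.grid(),
            saturation_counts=self.spectrometer.saturation_counts,
            scatter_coeff=self.optics.scatter_coeff,
            medium_scatter_equiv=self.optics.medium_scatter_equiv,
        )

    def led_bands(self) -> dict[str, Band]:
        return {
            ch.led_id: Band.around(ch.peak_nm, self.bands.led_halfwidth_nm)
            for ch in self.led_channels()
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=True)


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load and validate a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file {path} does not exist")
    data = yaml.safe_load(path.read_text()) or {}
    if not isinstance(data, dict):
        raise ConfigError("configuration must be a YAML mapping")
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        fields = ", ".join(
            ".".join(str(loc) for loc in err["loc"]) or "<root>"
            for err in exc.errors()
        )
        raise ConfigError(f"invalid configuration field(s): {fields}\n{exc}") from exc
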