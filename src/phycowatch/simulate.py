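"""Virtual photobioreactor: optical forward model and culture dynamics.

The simulator plays the role of the physical instrument behind the same
interface the acquisition protocol would use on real hardware.  It produces
90°-geometry spectra as the sum of

* a scattered excitation line — the LED emission profile scaled linearly by
  the total particle density (cells, contaminants, plus a constant
  medium/vial scattering floor), and
* Gaussian pigment emission bands, each proportional to biomass, per-cell
  pigment content, a transient fluorescence-yield factor, and the overlap of
  the LED line with the pigment's excitation band,

with optional Poisson shot noise and Gaussian read noise, clipped at the
detector full scale.  Culture trajectories cover logistic growth,
photoinhibition (transient yield pulse, pigment photo-degradation, eventual
cell death) and contamination by a non-fluorescent scatterer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .spectra import (
    Band,
    DEFAULT_FLUOR_BAND,
    DEFAULT_LED_HALFWIDTH_NM,
    DEFAULT_SATURATION_COUNTS,
    MeasurementPair,
    Spectrum,
    default_grid,
    fluorescence_index,
)

_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


def fwhm_to_sigma(fwhm_nm: float) -> float:
    return fwhm_nm / _FWHM_TO_SIGMA


def _gauss_unit_area(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mu) / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class LedChannel:
    """One excitation LED of the fiber-coupled bank."""

    led_id: str
    peak_nm: float
    fwhm_nm: float
    radiant_power_mw: float
    enabled: bool = True

    def __post_init__(self) -> None:
        if not self.fwhm_nm > 0:
            raise ValueError("fwhm_nm must be positive")
        if self.radiant_power_mw < 0:
            raise ValueError("radiant_power_mw must be non-negative")


@dataclass
class FluorophoreSpec:
    """Excitation/emission model of one fluorophore.

    ``excitation_max_nm`` lists one or more excitation maxima, primary
    first; secondary maxima contribute with half weight.  ``brightness`` is
    the relative emission per unit pigment, per cell/µL of biomass, per unit
    excitation overlap (detector counts·nm per second of exposure).
    """

    name: str
    excitation_max_nm: tuple[float, ...]
    excitation_width_nm: float
    emission_max_nm: float
    emission_width_nm: float
    brightness: float

    def __post_init__(self) -> None:
        self.excitation_max_nm = tuple(float(x) for x in self.excitation_max_nm)
        if not self.excitation_max_nm or any(x <= 0 for x in self.excitation_max_nm):
            raise ValueError("excitation maxima must be positive")
        if not self.emission_max_nm > self.excitation_max_nm[0]:
            raise ValueError("Stokes shift violated: emission must be redder "
                             "than the primary excitation maximum")

    @property
    def primary_excitation_nm(self) -> float:
        return self.excitation_max_nm[0]


@dataclass
class CultureState:
    """Instantaneous state of the vial contents."""

    biomass_cells_per_ul: float
    pigment_per_cell: dict[str, float] = field(
        default_factory=lambda: {"phycocyanin": 1.0, "chlorophyll_a": 0.4}
    )
    contaminant_cells_per_ul: float = 0.0
    yield_modifier: float = 1.0
    time_h: float = 0.0

    def __post_init__(self) -> None:
        if self.biomass_cells_per_ul < 0 or self.contaminant_cells_per_ul < 0:
            raise ValueError("densities must be non-negative")
        if any(v < 0 for v in self.pigment_per_cell.values()):
            raise ValueError("pigment contents must be non-negative")
        if self.yield_modifier < 0:
            raise ValueError("yield_modifier must be non-negative")


SCENARIOS = ("growth", "photoinhibition", "contamination", "calibration")


@dataclass
class ScenarioConfig:
    """Kinetic parameters of a simulated culture trajectory.

    Defaults describe a healthy exponential-phase cyanobacterial culture;
    the classmethod constructors flip on the condition-specific terms.
    Rates are per hour, densities in cells/µL, irradiance in
    µmol photons m⁻² s⁻¹.
    """

    scenario: str = "growth"
    growth_rate_per_h: float = 0.04
    carrying_capacity: float = 2000.0
    irradiance_umol: float = 80.0
    critical_irradiance_umol: float = 120.0
    pigment_decay_per_h: float = 0.15
    yield_pulse_amplitude: float = 0.6
    yield_pulse_decay_per_h: float = 0.5
    contaminant_growth_rate_per_h: float = 0.12
    viability_fraction: float = 0.3
    death_rate_per_h: float = 0.1
    initial_biomass_cells_per_ul: float = 200.0
    initial_contaminant_cells_per_ul: float = 0.0
    initial_pigment: dict[str, float] = field(
        default_factory=lambda: {"phycocyanin": 1.0, "chlorophyll_a": 0.4}
    )
    read_noise_sigma: float = 4.0
    shot_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ConfigError(
                f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}"
            )
        for name in ("growth_rate_per_h", "pigment_decay_per_h",
                     "yield_pulse_decay_per_h", "contaminant_growth_rate_per_h",
                     "death_rate_per_h"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if not self.carrying_capacity > 0:
            raise ConfigError("carrying_capacity must be positive")

    # -- condition presets -------------------------------------------------
    @classmethod
    def growth(cls, **kw) -> "ScenarioConfig":
        return cls(scenario="growth", **kw)

    @classmethod
    def photoinhibition(cls, **kw) -> "ScenarioConfig":
        kw.setdefault("irradiance_umol", 150.0)
        kw.setdefault("initial_biomass_cells_per_ul", 500.0)
        return cls(scenario="photoinhibition", **kw)

    @classmethod
    def contamination(cls, **kw) -> "ScenarioConfig":
        kw.setdefault("initial_biomass_cells_per_ul", 500.0)
        kw.setdefault("initial_contaminant_cells_per_ul", 20.0)
        return cls(scenario="contamination", **kw)

    @classmethod
    def calibration(cls, **kw) -> "ScenarioConfig":
        kw.setdefault("growth_rate_per_h", 0.0)
        return cls(scenario="calibration", **kw)

    def initial_state(self) -> CultureState:
        return CultureState(
            biomass_cells_per_ul=self.initial_biomass_cells_per_ul,
            pigment_per_cell=dict(self.initial_pigment),
            contaminant_cells_per_ul=self.initial_contaminant_cells_per_ul,
            yield_modifier=1.0,
            time_h=0.0,
        )


@dataclass
class OpticalModel:
    """Detector grid plus the coefficients of the optical forward model.

    ``scatter_coeff`` converts (radiant-power-weighted LED profile ×
    particle density × exposure) into detector counts.
    ``medium_scatter_equiv`` is the constant scattering background of medium
    and vial walls, expressed as an equivalent particle density, which keeps
    the excitation-line reference finite in a blank vial.
    """

    wavelengths_nm: np.ndarray = field(default_factory=default_grid)
    saturation_counts: float = DEFAULT_SATURATION_COUNTS
    fluorophores: dict[str, FluorophoreSpec] = field(default_factory=dict)
    scatter_coeff: float = 3.0
    medium_scatter_equiv: float = 5000.0
    read_noise_sigma: float = 4.0
    shot_noise: bool = True

    def __post_init__(self) -> None:
        if not self.fluorophores:
            from .library import FLUOROPHORES
            self.fluorophores = dict(FLUOROPHORES)

    def with_noise(self, read_noise_sigma: float, shot_noise: bool) -> "OpticalModel":
        return replace(self, read_noise_sigma=read_noise_sigma, shot_noise=shot_noise)


# ---------------------------------------------------------------------------
# Optical forward model
# ---------------------------------------------------------------------------

def led_emission(channel: LedChannel, grid: np.ndarray) -> np.ndarray:
    """Sampled LED emission profile: Gaussian at the channel peak whose
    integral over wavelength equals the radiant power (mW).  Disabled or
    zero-power channels emit nothing."""
    grid = np.asarray(grid, dtype=float)
    if not channel.enabled or channel.radiant_power_mw == 0:
        return np.zeros_like(grid)
    sigma = fwhm_to_sigma(channel.fwhm_nm)
    return channel.radiant_power_mw * _gauss_unit_area(grid, channel.peak_nm, sigma)


def excitation_efficiency(fluor: FluorophoreSpec, channel: LedChannel) -> float:
    """Overlap of the LED line with the fluorophore's excitation band(s).

    Computed in closed form as the integral of the unit-area LED Gaussian
    against a unit-peak Gaussian excitation band:
    ``(σ_ex/√(σ_led²+σ_ex²))·exp(−Δ²/(2(σ_led²+σ_ex²)))`` for peak
    separation Δ.  Secondary excitation maxima contribute with weight 0.5.
    The result lies in [0, 1] and decreases monotonically with Δ for
    single-band fluorophores.
    """
    s_led = fwhm_to_sigma(channel.fwhm_nm)
    s_ex = fwhm_to_sigma(fluor.excitation_width_nm)
    var = s_led**2 + s_ex**2
    total = 0.0
    for k, mu in enumerate(fluor.excitation_max_nm):
        weight = 1.0 if k == 0 else 0.5
        delta = channel.peak_nm - mu
        total += weight * (s_ex / math.sqrt(var)) * math.exp(-(delta**2) / (2 * var))
    return min(total, 1.0)


def expected_spectrum(
    state: CultureState,
    channel: LedChannel,
    exposure_s: float,
    optics: OpticalModel,
) -> np.ndarray:
    """Noise-free expected detector counts (unclipped) for one capture."""
    if not exposure_s > 0:
        raise ValueError("exposure_s must be positive")
    grid = optics.wavelengths_nm
    particles = (
        state.biomass_cells_per_ul
        + state.contaminant_cells_per_ul
        + optics.medium_scatter_equiv
    )
    counts = optics.scatter_coeff * particles * led_emission(channel, grid)
    for name, pigment in state.pigment_per_cell.items():
        spec = optics.fluorophores.get(name)
        if spec is None or pigment == 0 or state.biomass_cells_per_ul == 0:
            continue
        eff = excitation_efficiency(spec, channel)
        if eff <= 0:
            continue
        sigma_em = fwhm_to_sigma(spec.emission_width_nm)
        counts = counts + (
            spec.brightness
            * pigment
            * state.biomass_cells_per_ul
            * state.yield_modifier
            * eff
            * _gauss_unit_area(grid, spec.emission_max_nm, sigma_em)
        )
    return exposure_s * counts


def simulate_spectrum(
    state: CultureState,
    channel: LedChannel,
    exposure_s: float,
    optics: OpticalModel,
    rng: Optional[np.random.Generator] = None,
    timestamp: float = 0.0,
) -> Spectrum:
    """One simulated capture.  Pass ``rng=None`` for a noise-free readout;
    otherwise Poisson shot noise and Gaussian read noise are applied as
    configured in ``optics``.  Counts are clipped at the detector full scale
    and clipped samples are flagged saturated."""
    mu = expected_spectrum(state, channel, exposure_s, optics)
    counts = mu
    if rng is not None:
        if optics.shot_noise:
            # Normal approximation well above the detector ceiling keeps the
            # Poisson sampler away from huge lambdas; those samples clip anyway.
            big = mu > 10 * optics.saturation_counts
            counts = np.empty_like(mu)
            counts[~big] = rng.poisson(mu[~big]).astype(float)
            counts[big] = mu[big] + rng.standard_normal(int(big.sum())) * np.sqrt(mu[big])
        if optics.read_noise_sigma > 0:
            counts = counts + rng.normal(0.0, optics.read_noise_sigma, mu.shape)
    saturated = counts >= optics.saturation_counts
    counts = np.clip(counts, 0.0, optics.saturation_counts)
    return Spectrum(
        wavelengths_nm=optics.wavelengths_nm.copy(),
        intensities=counts,
        exposure_s=exposure_s,
        saturation_counts=optics.saturation_counts,
        timestamp=timestamp,
        led_id=channel.led_id,
        saturated=saturated,
    )


# ---------------------------------------------------------------------------
# Culture dynamics
# ---------------------------------------------------------------------------

def _yield_pulse(t_h: float, amplitude: float, decay_per_h: float) -> float:
    """Transient fluorescence-yield excursion after the onset of excess
    light: energy that damaged photosystems can no longer use is re-emitted
    as fluorescence for a few hours.  The pulse ``1 + A·(kt)·e^{1−kt}``
    rises from 1, peaks at ``1 + A`` at ``t = 1/k`` and relaxes back to 1.
    """
    u = decay_per_h * t_h
    return 1.0 + amplitude * u * math.exp(1.0 - u)


def step_culture(
    state: CultureState, config: ScenarioConfig, dt_h: float
) -> CultureState:
    """Advance the culture by one forward-Euler step of ``dt_h`` hours.

    growth
        Logistic biomass increase; pigments constant; yield 1.
    photoinhibition (irradiance above the critical level)
        Transient yield pulse, exponential pigment photo-degradation, and
        first-order biomass die-off once phycocyanin falls below the
        viability fraction of its healthy level.  Below the critical
        irradiance the culture simply grows.
    contamination
        Target biomass static with pigment loss at the configured rate; a
        non-fluorescent contaminant grows logistically and contributes to
        scattering only.
    calibration
        No dynamics.
    """
    if not dt_h > 0:
        raise ValueError("dt_h must be positive")
    if config.scenario not in SCENARIOS:
        raise ConfigError(f"unknown scenario {config.scenario!r}")

    t_next = state.time_h + dt_h
    b = state.biomass_cells_per_ul
    c = state.contaminant_cells_per_ul
    pig = dict(state.pigment_per_cell)
    yld = 1.0

    if config.scenario == "calibration":
        pass
    elif config.scenario == "growth" or (
        config.scenario == "photoinhibition"
        and config.irradiance_umol <= config.critical_irradiance_umol
    ):
        b += config.growth_rate_per_h * b * (1 - b / config.carrying_capacity) * dt_h
    elif config.scenario == "photoinhibition":
        yld = _yield_pulse(
            t_next, config.yield_pulse_amplitude, config.yield_pulse_decay_per_h
        )
        for name in pig:
            pig[name] = pig[name] * math.exp(-config.pigment_decay_per_h * dt_h)
        healthy = config.initial_pigment.get("phycocyanin", 1.0)
        if pig.get("phycocyanin", 0.0) < config.viability_fraction * healthy:
            b -= config.death_rate_per_h * b * dt_h
    elif config.scenario == "contamination":
        for name in pig:
            pig[name] = pig[name] * math.exp(-config.pigment_decay_per_h * dt_h)
        c += (
            config.contaminant_growth_rate_per_h
            * c
            * (1 - c / config.carrying_capacity)
            * dt_h
        )

    return CultureState(
        biomass_cells_per_ul=max(b, 0.0),
        pigment_per_cell=pig,
        contaminant_cells_per_ul=max(c, 0.0),
        yield_modifier=yld,
        time_h=t_next,
    )


def read_od(
    state: CultureState,
    rng: Optional[np.random.Generator] = None,
    od_per_cell: float = 1e-3,
    noise_sigma: float = 0.005,
) -> float:
    """Near-infrared optical-density reading: linear in total particle
    density (blind to scatterer identity) plus Gaussian noise."""
    od = od_per_cell * (state.biomass_cells_per_ul + state.contaminant_cells_per_ul)
    if rng is not None and noise_sigma > 0:
        od += rng.normal(0.0, noise_sigma)
    return float(od)


# ---------------------------------------------------------------------------
# Calibration series for LoD estimation
# ---------------------------------------------------------------------------

def generate_calibration_series(
    concentrations: Sequence[float],
    n_blanks: int,
    optics: Optional[OpticalModel] = None,
    channel: Optional[LedChannel] = None,
    rng: Optional[np.random.Generator] = None,
    short_s: float = 0.1,
    long_s: float = 5.0,
    fluor_band: Band = DEFAULT_FLUOR_BAND,
    pigment_per_cell: Optional[Mapping[str, float]] = None,
    replicates: int = 1,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Dilution-series fluorescence indices for LoD estimation.

    Runs the full dual-exposure pipeline on vials at each target-cell
    concentration (default pigment load, phycocyanin excitation channel) and
    on ``n_blanks`` blank vials.  Returns a ``(concentration, index)``
    DataFrame and the blank replicate indices.
    """
    if any(c < 0 for c in concentrations):
        raise ValueError("concentrations must be non-negative")
    if n_blanks < 3:
        raise ValueError("need at least 3 blank replicates")
    optics = optics or OpticalModel()
    if channel is None:
        from .library import get_led
        channel = get_led("615nm")
    led_band = Band.around(channel.peak_nm, DEFAULT_LED_HALFWIDTH_NM)
    pigments = dict(pigment_per_cell or {"phycocyanin": 1.0, "chlorophyll_a": 0.4})

    def one_index(conc: float) -> float:
        st = CultureState(biomass_cells_per_ul=conc, pigment_per_cell=pigments)
        short = simulate_spectrum(st, channel, short_s, optics, rng)
        long = simulate_spectrum(st, channel, long_s, optics, rng)
        pair = MeasurementPair(led_id=channel.led_id, short=short, long=long)
        return fluorescence_index(pair, fluor_band, led_band)

    rows = [
        {"concentration": float(conc), "index": one_index(conc)}
        for conc in concentrations
        for _ in range(replicates)
    ]
    blanks = np.array([one_index(0.0) for _ in range(n_blanks)])
    return pd.DataFrame(rows), blanks
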