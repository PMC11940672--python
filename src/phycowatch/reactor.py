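"""Simulated reactor backend implementing the instrument contract.

This is the only backend shipped with the package; a physical reactor would
implement the same :class:`~phycowatch.acquisition.InstrumentBackend`
protocol on top of real drivers.  The simulated backend owns a culture
state, advances it on a simulated clock (so a 24 h run completes in well
under a second of wall time), and renders spectra through the optical
forward model.  It also enforces the optical mutual-exclusion rules: at no
instant may two excitation LEDs, or an excitation LED and the photoperiod
lights, be on together.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .acquisition import ReactorJobs
from .errors import AcquisitionError, ConfigError
from .simulate import (
    CultureState,
    LedChannel,
    OpticalModel,
    ScenarioConfig,
    read_od,
    simulate_spectrum,
    step_culture,
)
from .spectra import Spectrum

#: Forward-Euler step of the culture integrator (hours).
DEFAULT_DT_H = 0.1


class SimulatedReactor:
    """Virtual stirred mini photobioreactor with a fluorescence bench.

    Parameters
    ----------
    scenario
        Culture kinetics to simulate.
    optics
        Optical forward model; its noise settings are overridden by the
        scenario's noise configuration.
    channels
        Excitation LED bank (defaults to the built-in six-channel bank).
    rng
        Random generator; defaults to one seeded from ``scenario.seed``.
    dt_h
        Culture integrator step.
    """

    def __init__(
        self,
        scenario: Optional[ScenarioConfig] = None,
        optics: Optional[OpticalModel] = None,
        channels: Optional[Sequence[LedChannel]] = None,
        rng: Optional[np.random.Generator] = None,
        dt_h: float = DEFAULT_DT_H,
    ) -> None:
        self.scenario = scenario or ScenarioConfig()
        base_optics = optics or OpticalModel()
        self.optics = base_optics.with_noise(
            self.scenario.read_noise_sigma, self.scenario.shot_noise
        )
        if channels is None:
            from .library import led_bank
            channels = led_bank()
        self.channels: list[LedChannel] = list(channels)
        self.rng = rng if rng is not None else np.random.default_rng(self.scenario.seed)
        self.dt_h = dt_h
        self.state: CultureState = self.scenario.initial_state()
        self._jobs = ReactorJobs()
        self._clock_h = 0.0
        self._pending_h = 0.0  # time advanced since the last integrator step
        self._leds_on: set[str] = set()
        self.events: list[tuple[float, str]] = []

    # -- clock & culture ---------------------------------------------------
    @property
    def clock_h(self) -> float:
        return self._clock_h

    def sleep_until(self, time_h: float) -> None:
        """Advance the simulated clock, integrating the culture in ``dt_h``
        chunks (partial chunks accumulate until a full step is due)."""
        if time_h < self._clock_h - 1e-12:
            raise ValueError("simulated clock cannot run backwards")
        self._pending_h += time_h - self._clock_h
        self._clock_h = time_h
        while self._pending_h >= self.dt_h - 1e-12:
            self.state = step_culture(self.state, self.scenario, self.dt_h)
            self._pending_h -= self.dt_h

    # -- jobs & actuators --------------------------------------------------
    @property
    def jobs(self) -> ReactorJobs:
        return self._jobs

    @property
    def led_ids(self) -> list[str]:
        return [ch.led_id for ch in self.channels if ch.enabled]

    def _event(self, what: str) -> None:
        self.events.append((self._clock_h, what))

    def set_led(self, led_id: str, on: bool) -> None:
        if led_id not in {ch.led_id for ch in self.channels}:
            raise ConfigError(f"unknown LED channel {led_id!r}")
        if on:
            others = self._leds_on - {led_id}
            if others:
                raise AcquisitionError(
                    f"mutual exclusion violated: {sorted(others)} already on"
                )
            if self._jobs.photoperiod_lights:
                raise AcquisitionError(
                    "mutual exclusion violated: photoperiod lights are on"
                )
            self._leds_on.add(led_id)
            self._event(f"led_on:{led_id}")
        else:
            self._leds_on.discard(led_id)
            self._event(f"led_off:{led_id}")

    def set_photoperiod_lights(self, on: bool) -> None:
        if on and self._leds_on:
            raise AcquisitionError(
                "mutual exclusion violated: an excitation LED is on"
            )
        self._jobs.photoperiod_lights = on
        self._event(f"photoperiod:{'on' if on else 'off'}")

    def pause_od(self) -> None:
        self._jobs.od_job = "paused"
        self._event("od:paused")

    def resume_od(self) -> None:
        self._jobs.od_job = "running"
        self._event("od:running")

    # -- measurements ------------------------------------------------------
    def capture(self, exposure_s: float) -> Spectrum:
        """Read out the spectrometer with the currently active LED (a dark
        capture when none is on)."""
        if len(self._leds_on) > 1:  # pragma: no cover - guarded by set_led
            raise AcquisitionError("more than one excitation LED on")
        if self._leds_on:
            led_id = next(iter(self._leds_on))
            channel = next(ch for ch in self.channels if ch.led_id == led_id)
        else:
            channel = LedChannel(
                led_id="none", peak_nm=615.0, fwhm_nm=20.0,
                radiant_power_mw=0.0, enabled=False,
            )
        return simulate_spectrum(
            self.state, channel, exposure_s, self.optics,
            rng=self.rng, timestamp=self._clock_h,
        )

    def read_od(self) -> float:
        return read_od(self.state, rng=self.rng)
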