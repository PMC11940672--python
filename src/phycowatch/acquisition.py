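"""The measurement protocol: scheduled dual-exposure rounds.

A round pauses jobs that would corrupt the optics (the near-infrared OD
reader), forces the photoperiod lights off, drives each enabled excitation
LED strictly one at a time, captures a short exposure (unsaturated
excitation line) and a long exposure (fluorescence) per LED, and restores
the prior job/light state afterwards — guaranteed, even on instrument
failure mid-round.  ``run_monitor`` repeats rounds at a fixed cadence on the
run clock, logging OD between rounds and appending a scattering-corrected
fluorescence index per LED after each round.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Protocol, Sequence, runtime_checkable

import numpy as np

from .errors import (
    AcquisitionError,
    CaptureError,
    ConfigError,
    SchedulingError,
    SinkError,
)
from .spectra import (
    Band,
    DEFAULT_FLUOR_BAND,
    DEFAULT_LED_HALFWIDTH_NM,
    MeasurementPair,
    Spectrum,
    fluorescence_index,
)

logger = logging.getLogger(__name__)

#: Default exposure pair (seconds): short capture for the excitation line,
#: long capture for the fluorescence band.
DEFAULT_SHORT_EXPOSURE_S = 0.1
DEFAULT_LONG_EXPOSURE_S = 5.0


@dataclass
class ReactorJobs:
    """Job/actuator state of the reactor that a round must preserve."""

    od_job: str = "running"  # "running" | "paused"
    photoperiod_lights: bool = True
    stirring_rpm: float = 500.0
    photoperiod_schedule: tuple[float, float] = (16.0, 8.0)

    def __post_init__(self) -> None:
        if self.od_job not in ("running", "paused"):
            raise ValueError("od_job must be 'running' or 'paused'")
        if not 100.0 <= self.stirring_rpm <= 1000.0:
            raise ValueError("stirring_rpm must lie in [100, 1000]")
        if abs(sum(self.photoperiod_schedule) - 24.0) > 1e-9:
            raise ValueError("photoperiod light:dark hours must sum to 24")

    def snapshot(self) -> "ReactorJobs":
        return replace(self)


@runtime_checkable
class InstrumentBackend(Protocol):
    """Contract any reactor backend (simulated or physical) must satisfy."""

    @property
    def jobs(self) -> ReactorJobs: ...
    @property
    def led_ids(self) -> list[str]: ...
    @property
    def clock_h(self) -> float: ...

    def set_led(self, led_id: str, on: bool) -> None: ...
    def set_photoperiod_lights(self, on: bool) -> None: ...
    def pause_od(self) -> None: ...
    def resume_od(self) -> None: ...
    def capture(self, exposure_s: float) -> Spectrum: ...
    def read_od(self) -> float: ...
    def sleep_until(self, time_h: float) -> None: ...


def measurement_round(
    backend: InstrumentBackend,
    leds: Sequence[str],
    short_s: float = DEFAULT_SHORT_EXPOSURE_S,
    long_s: float = DEFAULT_LONG_EXPOSURE_S,
    round_index: int = 0,
) -> list[MeasurementPair]:
    """Execute one dual-exposure round over the given LED channels.

    The pre-round job state is restored unconditionally.  On a capture
    failure the round is aborted: completed pairs are kept, the failing LED
    (and any remaining ones) are dropped, and the failure is logged.
    """
    if not leds:
        raise ValueError("leds must be a non-empty list of channel ids")
    known = set(backend.led_ids)
    unknown = [led for led in leds if led not in known]
    if unknown:
        raise ConfigError(f"unknown LED channel(s): {unknown}")
    if not 0 < short_s < long_s:
        raise ValueError("need 0 < short_s < long_s")

    before = backend.jobs.snapshot()
    pairs: list[MeasurementPair] = []
    try:
        backend.set_photoperiod_lights(False)
        if before.od_job == "running":
            backend.pause_od()
        for led in leds:
            backend.set_led(led, True)
            try:
                short = backend.capture(short_s)
                long = backend.capture(long_s)
            except CaptureError as exc:
                logger.error(
                    "round %d: capture failed on LED %s: %s; aborting round",
                    round_index, led, exc,
                )
                break
            finally:
                backend.set_led(led, False)
            pairs.append(
                MeasurementPair(
                    led_id=led,
                    short=short,
                    long=long,
                    round_index=round_index,
                    timestamp=backend.clock_h,
                )
            )
    finally:
        backend.set_photoperiod_lights(before.photoperiod_lights)
        if before.od_job == "running":
            backend.resume_od()
    return pairs


class RunSink(Protocol):
    """Destination for run artifacts (directory writer or in-memory)."""

    def write_pair(self, pair: MeasurementPair) -> None: ...
    def append_index(self, time_h: float, round_index: int,
                     led_id: str, index: float) -> None: ...
    def append_od(self, time_h: float, od: float) -> None: ...
    def log(self, message: str, round_index: Optional[int] = None) -> None: ...


class MemorySink:
    """In-memory sink; primarily for analysis pipelines and tests."""

    def __init__(self) -> None:
        self.pairs: list[MeasurementPair] = []
        self.index_rows: list[tuple[float, int, str, float]] = []
        self.od_rows: list[tuple[float, float]] = []
        self.log_lines: list[str] = []

    def write_pair(self, pair: MeasurementPair) -> None:
        self.pairs.append(pair)

    def append_index(self, time_h, round_index, led_id, index) -> None:
        self.index_rows.append((time_h, round_index, led_id, index))

    def append_od(self, time_h, od) -> None:
        self.od_rows.append((time_h, od))

    def log(self, message, round_index=None) -> None:
        self.log_lines.append(message)


@dataclass
class RunLog:
    """Summary of a monitoring run."""

    rounds_completed: int
    pairs_captured: int
    failures: list[str] = field(default_factory=list)
    index_rows: list[tuple[float, int, str, float]] = field(default_factory=list)
    od_rows: list[tuple[float, float]] = field(default_factory=list)

    def series(self, led_id: str):
        """FluorSeries of one LED, with OD interpolated at round times."""
        from .analytics import FluorSeries

        rows = [r for r in self.index_rows if r[2] == led_id]
        if not rows:
            raise ValueError(f"no index rows for LED {led_id!r}")
        times = np.array([r[0] for r in rows])
        values = np.array([r[3] for r in rows])
        if self.od_rows:
            od_t = np.array([r[0] for r in self.od_rows])
            od_v = np.array([r[1] for r in self.od_rows])
            od = np.interp(times, od_t, od_v)
        else:
            od = np.full_like(times, np.nan)
        return FluorSeries(times_h=times, index_values=values,
                           od_values=od, led_id=led_id)


def run_monitor(
    backend: InstrumentBackend,
    schedule_interval_min: float,
    duration_h: float,
    sink: RunSink,
    leds: Optional[Sequence[str]] = None,
    short_s: float = DEFAULT_SHORT_EXPOSURE_S,
    long_s: float = DEFAULT_LONG_EXPOSURE_S,
    fluor_band: Band = DEFAULT_FLUOR_BAND,
    led_bands: Optional[Mapping[str, Band]] = None,
    od_cadence_s: float = 5.0,
) -> RunLog:
    """Run the monitoring schedule on the backend's (simulated) clock.

    Rounds start at t = 0 and repeat every ``schedule_interval_min``; OD is
    logged at ``od_cadence_s`` between rounds.  After each round the
    fluorescence index of every captured pair is appended to the sink.  A
    sink write is retried once; a second failure aborts the run with the
    partial data intact.
    """
    leds = list(leds) if leds is not None else list(backend.led_ids)
    if not leds:
        raise ValueError("no LED channels to drive")
    round_duration_h = len(leds) * (short_s + long_s) / 3600.0
    interval_h = schedule_interval_min / 60.0
    if interval_h <= round_duration_h:
        raise SchedulingError(
            f"interval {schedule_interval_min} min shorter than one round "
            f"({round_duration_h * 60:.2f} min)"
        )
    if led_bands is None:
        led_bands = {}

    def _sink(op, *args) -> None:
        try:
            op(*args)
        except (OSError, SinkError):
            logger.warning("sink write failed; retrying once")
            op(*args)  # second failure propagates

    round_times = np.arange(0.0, duration_h, interval_h)
    od_step_h = od_cadence_s / 3600.0
    log = RunLog(rounds_completed=0, pairs_captured=0)

    try:
        for round_index, t_round in enumerate(round_times):
            # OD logging between the previous round and this one.
            t = backend.clock_h
            while t < t_round - 1e-12:
                t = min(t + od_step_h, t_round)
                backend.sleep_until(t)
                od = backend.read_od()
                log.od_rows.append((backend.clock_h, od))
                _sink(sink.append_od, backend.clock_h, od)
            backend.sleep_until(t_round)
            od = backend.read_od()
            log.od_rows.append((backend.clock_h, od))
            _sink(sink.append_od, backend.clock_h, od)

            pairs = measurement_round(
                backend, leds, short_s=short_s, long_s=long_s,
                round_index=round_index,
            )
            if len(pairs) < len(leds):
                msg = (f"round {round_index}: aborted after "
                       f"{len(pairs)}/{len(leds)} LEDs")
                log.failures.append(msg)
                _sink(sink.log, msg, round_index)
            for pair in pairs:
                _sink(sink.write_pair, pair)
                band = led_bands.get(
                    pair.led_id,
                    _default_led_band(backend, pair.led_id),
                )
                idx = fluorescence_index(pair, fluor_band, band)
                _sink(sink.append_index, t_round, round_index, pair.led_id, idx)
                log.index_rows.append((t_round, round_index, pair.led_id, idx))
            log.pairs_captured += len(pairs)
            log.rounds_completed += 1
            _sink(
                sink.log,
                f"round {round_index} complete: {len(pairs)} pair(s)",
                round_index,
            )
    except (OSError, SinkError) as exc:
        msg = f"sink failure after retry, aborting run: {exc}"
        logger.error(msg)
        log.failures.append(msg)
        return log

    # Trailing OD log up to the end of the run.
    t = backend.clock_h
    while t < duration_h - 1e-12:
        t = min(t + od_step_h, duration_h)
        backend.sleep_until(t)
        od = backend.read_od()
        log.od_rows.append((backend.clock_h, od))
        try:
            _sink(sink.append_od, backend.clock_h, od)
        except (OSError, SinkError) as exc:
            log.failures.append(f"sink failure after retry: {exc}")
            return log
    return log


def _default_led_band(backend: InstrumentBackend, led_id: str) -> Band:
    """Excitation-line window: LED peak ± 10 nm, from the backend's channel
    table when available, else parsed from ids like ``"615nm"``."""
    peak = None
    channels = getattr(backend, "channels", None)
    if channels:
        for ch in channels:
            if ch.led_id == led_id:
                peak = ch.peak_nm
                break
    if peak is None:
        digits = "".join(c for c in led_id if c.isdigit() or c == ".")
        if not digits:
            raise ConfigError(f"cannot infer peak wavelength for LED {led_id!r}")
        peak = float(digits)
    return Band.around(peak, DEFAULT_LED_HALFWIDTH_NM)
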