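"""Run persistence: spectra CSVs with JSON sidecars, index/OD logs, export.

Layout of a run directory::

    rundir/
      spectra/round<NNN>_<led>_<short|long>.csv   (+ .meta.json sidecar)
      fluorescence_index.csv                       time_h,round,led_id,index
      od_readings.csv                              time_h,od
      run_config.yaml                              config snapshot
      run.log                                      timestamped event log
      manifest.json                                written by export_run

Floats are serialized at 9 significant digits, which round-trips the
quantities of interest at the text precision.
"""

from __future__ import annotations

import json
import re
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .errors import SinkError
from .spectra import MeasurementPair, Spectrum

_FMT = "%.9g"


def _fmt(x: float) -> str:
    return _FMT % float(x)


# ---------------------------------------------------------------------------
# Spectrum round trip
# ---------------------------------------------------------------------------

def save_spectrum(spectrum: Spectrum, csv_path: Union[str, Path]) -> Path:
    """Write a spectrum as ``wavelength_nm,intensity`` CSV plus a JSON
    metadata sidecar (``<name>.meta.json``)."""
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["wavelength_nm,intensity"]
    lines += [
        f"{_fmt(w)},{_fmt(i)}"
        for w, i in zip(spectrum.wavelengths_nm, spectrum.intensities)
    ]
    csv_path.write_text("\n".join(lines) + "\n")
    meta = {
        "exposure_s": spectrum.exposure_s,
        "led_id": spectrum.led_id,
        "timestamp": spectrum.timestamp,
        "saturation_counts": spectrum.saturation_counts,
        "saturated_indices": (
            [] if spectrum.saturated is None
            else np.flatnonzero(spectrum.saturated).tolist()
        ),
    }
    sidecar_path(csv_path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return csv_path


def sidecar_path(csv_path: Union[str, Path]) -> Path:
    csv_path = Path(csv_path)
    return csv_path.with_name(csv_path.stem + ".meta.json")


def load_spectrum(csv_path: Union[str, Path]) -> Spectrum:
    """Inverse of :func:`save_spectrum`."""
    csv_path = Path(csv_path)
    data = np.genfromtxt(csv_path, delimiter=",", skip_header=1, dtype=float)
    data = np.atleast_2d(data)
    meta = json.loads(sidecar_path(csv_path).read_text())
    n = data.shape[0]
    saturated = np.zeros(n, dtype=bool)
    saturated[np.asarray(meta.get("saturated_indices", []), dtype=int)] = True
    return Spectrum(
        wavelengths_nm=data[:, 0],
        intensities=data[:, 1],
        exposure_s=float(meta["exposure_s"]),
        saturation_counts=float(meta["saturation_counts"]),
        timestamp=float(meta["timestamp"]),
        led_id=str(meta["led_id"]),
        saturated=saturated if saturated.any() else None,
    )


# ---------------------------------------------------------------------------
# Run directory sink
# ---------------------------------------------------------------------------

class RunDirSink:
    """Write-through sink persisting run artifacts into a directory."""

    def __init__(self, rundir: Union[str, Path],
                 config_snapshot: Optional[str] = None) -> None:
        self.rundir = Path(rundir)
        (self.rundir / "spectra").mkdir(parents=True, exist_ok=True)
        self.index_path = self.rundir / "fluorescence_index.csv"
        self.od_path = self.rundir / "od_readings.csv"
        self.log_path = self.rundir / "run.log"
        self.index_path.write_text("time_h,round,led_id,index\n")
        self.od_path.write_text("time_h,od\n")
        self.log_path.write_text("")
        if config_snapshot is not None:
            (self.rundir / "run_config.yaml").write_text(config_snapshot)

    def _spectrum_name(self, pair: MeasurementPair, which: str) -> str:
        return f"round{pair.round_index:03d}_{pair.led_id}_{which}.csv"

    def write_pair(self, pair: MeasurementPair) -> None:
        try:
            save_spectrum(pair.short,
                          self.rundir / "spectra" / self._spectrum_name(pair, "short"))
            save_spectrum(pair.long,
                          self.rundir / "spectra" / self._spectrum_name(pair, "long"))
        except OSError as exc:
            raise SinkError(str(exc)) from exc

    def append_index(self, time_h: float, round_index: int,
                     led_id: str, index: float) -> None:
        try:
            with self.index_path.open("a") as fh:
                fh.write(f"{_fmt(time_h)},{round_index},{led_id},{_fmt(index)}\n")
        except OSError as exc:
            raise SinkError(str(exc)) from exc

    def append_od(self, time_h: float, od: float) -> None:
        try:
            with self.od_path.open("a") as fh:
                fh.write(f"{_fmt(time_h)},{_fmt(od)}\n")
        except OSError as exc:
            raise SinkError(str(exc)) from exc

    def log(self, message: str, round_index: Optional[int] = None) -> None:
        stamp = datetime.now(timezone.utc).isoformat(timespec="seconds")
        tag = "-" if round_index is None else str(round_index)
        try:
            with self.log_path.open("a") as fh:
                fh.write(f"{stamp} round={tag} {message}\n")
        except OSError as exc:
            raise SinkError(str(exc)) from exc


_SPECTRUM_RE = re.compile(r"round(\d+)_(.+)_(short|long)\.csv$")


def export_run(rundir: Union[str, Path]) -> dict:
    """Validate a run directory and write a deterministic ``manifest.json``.

    The manifest counts spectra and index rows per round and flags rounds
    whose dual-exposure pairs are incomplete (e.g. after an aborted round).
    Re-running export on the same directory is idempotent.
    """
    rundir = Path(rundir)
    if not rundir.is_dir():
        raise FileNotFoundError(f"run directory {rundir} does not exist")
    spectra_dir = rundir / "spectra"
    rounds: dict[int, dict[str, set[str]]] = {}
    n_spectra = 0
    if spectra_dir.is_dir():
        for path in sorted(spectra_dir.glob("*.csv")):
            m = _SPECTRUM_RE.match(path.name)
            if not m:
                continue
            n_spectra += 1
            rnd, led, which = int(m.group(1)), m.group(2), m.group(3)
            rounds.setdefault(rnd, {}).setdefault(led, set()).add(which)

    incomplete = sorted(
        rnd for rnd, leds in rounds.items()
        if any(kinds != {"short", "long"} for kinds in leds.values())
    )
    index_rows = 0
    index_path = rundir / "fluorescence_index.csv"
    if index_path.exists():
        index_rows = max(len(index_path.read_text().strip().splitlines()) - 1, 0)
    od_rows = 0
    od_path = rundir / "od_readings.csv"
    if od_path.exists():
        od_rows = max(len(od_path.read_text().strip().splitlines()) - 1, 0)

    manifest = {
        "n_rounds": len(rounds),
        "n_spectra_files": n_spectra,
        "n_index_rows": index_rows,
        "n_od_rows": od_rows,
        "incomplete_rounds": incomplete,
        "complete": not incomplete,
    }
    (rundir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )
    return manifest
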