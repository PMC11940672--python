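"""Wavelength-indexed spectra and the deterministic processing operators.

Everything downstream — acquisition, simulation, analytics — works on the
:class:`Spectrum` container defined here.  The operators implement the
scattering-corrected fluorescence index used for culture monitoring: a long
exposure captures the (weak) pigment fluorescence while saturating the
directly scattered excitation line, a short exposure captures the unsaturated
excitation line, and dividing the per-second fluorescence band integral by
the per-second excitation-band integral cancels the density-dependent
scattering seen by the 90° collection fiber.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import (
    BandRangeError,
    InsufficientDataError,
    NormalizationError,
    SaturationError,
)

#: Detector full scale of the virtual 16-bit spectrometer (counts).
DEFAULT_SATURATION_COUNTS = 65535.0

#: Fraction of full scale above which a sample is treated as saturated.
DEFAULT_SATURATION_THRESHOLD = 0.98


def default_grid(lo_nm: float = 225.0, hi_nm: float = 1000.0,
                 step_nm: float = 1.5) -> np.ndarray:
    """Wavelength grid of the virtual spectrometer (225–1000 nm, 1.5 nm)."""
    if not (lo_nm < hi_nm and step_nm > 0):
        raise ValueError("need lo_nm < hi_nm and step_nm > 0")
    n = int(math.floor((hi_nm - lo_nm) / step_nm)) + 1
    return lo_nm + step_nm * np.arange(n)


@dataclass(frozen=True)
class Band:
    """Closed wavelength interval [lo_nm, hi_nm] used as an integration
    window (the excitation-line window or the pigment emission window)."""

    lo_nm: float
    hi_nm: float

    def __post_init__(self) -> None:
        if not self.lo_nm < self.hi_nm:
            raise ValueError(f"Band requires lo < hi, got [{self.lo_nm}, {self.hi_nm}]")

    @classmethod
    def around(cls, center_nm: float, halfwidth_nm: float) -> "Band":
        return cls(center_nm - halfwidth_nm, center_nm + halfwidth_nm)

    @property
    def width_nm(self) -> float:
        return self.hi_nm - self.lo_nm


#: Phycocyanin emission window.  Centered near the observed ~657 nm peak and
#: clear of the 615 nm excitation-line window (605–625 nm).
DEFAULT_FLUOR_BAND = Band(640.0, 680.0)

#: Half-width of the excitation-line window around each LED peak.
DEFAULT_LED_HALFWIDTH_NM = 10.0


@dataclass
class Spectrum:
    """One detector readout: intensities on an ascending wavelength grid.

    Parameters
    ----------
    wavelengths_nm
        Strictly ascending sample positions (nm).
    intensities
        Detector counts, one per sample, in ``[0, saturation_counts]``.
    exposure_s
        Exposure time of the readout (s, > 0).
    saturation_counts
        Detector full scale.
    timestamp
        Acquisition time on the run clock (hours).
    led_id
        Identifier of the active excitation channel, or ``"none"``.
    saturated
        Optional per-sample flags marking values that hit full scale in the
        original readout; such samples are invalid for quantitation even
        after exposure rescaling.
    """

    wavelengths_nm: np.ndarray
    intensities: np.ndarray
    exposure_s: float
    saturation_counts: float = DEFAULT_SATURATION_COUNTS
    timestamp: float = 0.0
    led_id: str = "none"
    saturated: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths_nm.ndim != 1 or self.intensities.ndim != 1:
            raise ValueError("wavelengths and intensities must be 1-D")
        if len(self.wavelengths_nm) != len(self.intensities):
            raise ValueError("wavelengths and intensities length mismatch")
        if len(self.wavelengths_nm) > 1 and not np.all(np.diff(self.wavelengths_nm) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not self.exposure_s > 0:
            raise ValueError("exposure_s must be positive")
        if len(self.intensities) and (
            self.intensities.min() < 0.0
            or self.intensities.max() > self.saturation_counts * (1 + 1e-12)
        ):
            raise ValueError("intensities must lie in [0, saturation_counts]")
        if self.saturated is not None:
            self.saturated = np.asarray(self.saturated, dtype=bool)
            if len(self.saturated) != len(self.intensities):
                raise ValueError("saturated flag length mismatch")

    def __len__(self) -> int:
        return len(self.wavelengths_nm)

    def copy(self) -> "Spectrum":
        return replace(
            self,
            wavelengths_nm=self.wavelengths_nm.copy(),
            intensities=self.intensities.copy(),
            saturated=None if self.saturated is None else self.saturated.copy(),
        )


@dataclass
class MeasurementPair:
    """The two captures taken per LED in one round: a short exposure for the
    unsaturated excitation line and a long exposure for the fluorescence."""

    led_id: str
    short: Spectrum
    long: Spectrum
    round_index: int = 0
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        if not self.short.exposure_s < self.long.exposure_s:
            raise ValueError("short exposure must be shorter than long exposure")
        if self.short.led_id != self.long.led_id:
            raise ValueError("pair spectra must share the same led_id")
        if len(self.short) != len(self.long) or not np.allclose(
            self.short.wavelengths_nm, self.long.wavelengths_nm
        ):
            raise ValueError("pair spectra must share the wavelength grid")


def mask_saturated(
    spectrum: Spectrum,
    threshold_fraction: float = DEFAULT_SATURATION_THRESHOLD,
) -> np.ndarray:
    """Boolean mask, true where a sample is at/above the saturation cutoff.

    Samples already flagged saturated at acquisition stay masked regardless
    of their stored value.  The input spectrum is not modified.
    """
    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold_fraction must be in (0, 1]")
    mask = spectrum.intensities >= threshold_fraction * spectrum.saturation_counts
    if spectrum.saturated is not None:
        mask = mask | spectrum.saturated
    return mask


def band_integral(
    spectrum: Spectrum,
    band: Band,
    exclude_mask: Optional[np.ndarray] = None,
) -> float:
    """Trapezoidal integral (counts·nm) of intensity over a band.

    Masked samples are removed before integration (the trapezoid then spans
    the surviving, possibly non-uniform, grid).  Fewer than two usable
    samples yield 0.0 by convention.
    """
    wl = spectrum.wavelengths_nm
    if len(wl) == 0:
        raise BandRangeError("cannot integrate an empty spectrum")
    if band.lo_nm < wl[0] or band.hi_nm > wl[-1]:
        raise BandRangeError(
            f"band [{band.lo_nm}, {band.hi_nm}] outside spectrum range "
            f"[{wl[0]}, {wl[-1]}]"
        )
    sel = (wl >= band.lo_nm) & (wl <= band.hi_nm)
    if exclude_mask is not None:
        exclude_mask = np.asarray(exclude_mask, dtype=bool)
        if len(exclude_mask) != len(wl):
            raise ValueError("exclude_mask length mismatch")
        sel &= ~exclude_mask
    if sel.sum() < 2:
        return 0.0
    return float(np.trapezoid(spectrum.intensities[sel], wl[sel]))


def normalize_exposure(
    spectrum: Spectrum,
    target_exposure_s: float,
    saturation_threshold: float = DEFAULT_SATURATION_THRESHOLD,
) -> Spectrum:
    """Rescale intensities to a target exposure, assuming detector linearity.

    Saturated samples cannot be linearly rescaled: they keep their clipped
    value and are flagged, so downstream quantitation excludes them instead
    of trusting fabricated counts.  Unsaturated samples whose rescaled value
    would exceed full scale are clipped and flagged the same way.
    """
    if not target_exposure_s > 0:
        raise ValueError("target_exposure_s must be positive")
    scale = target_exposure_s / spectrum.exposure_s
    sat = mask_saturated(spectrum, saturation_threshold)
    scaled = spectrum.intensities * scale
    scaled[sat] = spectrum.intensities[sat]
    overflow = scaled > spectrum.saturation_counts
    scaled[overflow] = spectrum.saturation_counts
    return replace(
        spectrum,
        intensities=scaled,
        exposure_s=target_exposure_s,
        saturated=sat | overflow,
    )


def find_peak(
    spectrum: Spectrum,
    search_band: Band,
    exclude_mask: Optional[np.ndarray] = None,
) -> tuple[float, float]:
    """Locate the highest unmasked sample in a band.

    When the maximum is interior to the usable samples the position is
    refined by a three-point parabola through the maximum and its
    neighbours; at a boundary the raw sample is returned.  Ties break toward
    the shorter wavelength.

    Returns ``(wavelength_nm, height_counts)``.
    """
    wl = spectrum.wavelengths_nm
    if len(wl) == 0 or search_band.lo_nm < wl[0] or search_band.hi_nm > wl[-1]:
        raise BandRangeError("search band outside spectrum range")
    sel = (wl >= search_band.lo_nm) & (wl <= search_band.hi_nm)
    if exclude_mask is not None:
        sel &= ~np.asarray(exclude_mask, dtype=bool)
    x = wl[sel]
    y = spectrum.intensities[sel]
    if len(x) < 3:
        raise InsufficientDataError(
            f"need >= 3 usable samples in band, have {len(x)}"
        )
    i = int(np.argmax(y))  # argmax takes the first maximum -> shorter wavelength
    if i == 0 or i == len(x) - 1:
        return float(x[i]), float(y[i])
    # Parabola through the three points (handles non-uniform spacing after
    # masking); fall back to the raw sample for degenerate/convex fits.
    coeffs = np.polyfit(x[i - 1:i + 2] - x[i], y[i - 1:i + 2], 2)
    a, b, c = coeffs
    if a >= 0:
        return float(x[i]), float(y[i])
    dx = -b / (2 * a)
    dx = float(np.clip(dx, x[i - 1] - x[i], x[i + 1] - x[i]))
    return float(x[i] + dx), float(a * dx * dx + b * dx + c)


def fluorescence_index(
    pair: MeasurementPair,
    fluor_band: Band = DEFAULT_FLUOR_BAND,
    led_band: Band = Band.around(615.0, DEFAULT_LED_HALFWIDTH_NM),
    saturation_threshold: float = DEFAULT_SATURATION_THRESHOLD,
    mode: str = "area",
) -> float:
    """Scattering-corrected fluorescence index of one dual-exposure pair.

    ``(fluorescence band, counts·nm/s, long exposure)`` divided by
    ``(excitation band, counts·nm/s, short exposure)``.  Saturated samples
    are excluded from both integrals, and the ratio is invariant under any
    common multiplicative detector gain.  ``mode="height"`` uses interpolated
    peak heights (counts/s) instead of band areas.

    Raises
    ------
    SaturationError
        The fluorescence band is fully saturated in the long capture.
    NormalizationError
        The excitation-line reference is not positive.
    """
    if mode not in ("area", "height"):
        raise ValueError("mode must be 'area' or 'height'")
    short_mask = mask_saturated(pair.short, saturation_threshold)
    long_mask = mask_saturated(pair.long, saturation_threshold)

    wl = pair.long.wavelengths_nm
    in_fluor = (wl >= fluor_band.lo_nm) & (wl <= fluor_band.hi_nm)
    if in_fluor.any() and np.all(long_mask[in_fluor]):
        raise SaturationError("fluorescence band fully saturated in long capture")

    if mode == "area":
        led_val = band_integral(pair.short, led_band, short_mask)
        fluor_val = band_integral(pair.long, fluor_band, long_mask)
    else:
        led_val = find_peak(pair.short, led_band, short_mask)[1]
        fluor_val = find_peak(pair.long, fluor_band, long_mask)[1]

    led_rate = led_val / pair.short.exposure_s
    if led_rate <= 0:
        raise NormalizationError(
            "excitation-line reference is not positive; index undefined"
        )
    return (fluor_val / pair.long.exposure_s) / led_rate
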