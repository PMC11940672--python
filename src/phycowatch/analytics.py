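"""Culture-state analytics over fluorescence/OD time series.

Turbidity (OD) alone cannot tell a thriving target culture from an overrun
one, because the near-infrared scattering reading is blind to the identity
of the scatterer.  Pairing it with the scattering-corrected phycocyanin
fluorescence index disambiguates the common failure modes:

======  ============  =======================================
OD      fluorescence  verdict
======  ============  =======================================
rising  rising        healthy_growth
rising  falling       contamination (non-fluorescent invader)
falling falling       degradation (e.g. photoinhibition)
other   other         indeterminate
======  ============  =======================================

The module also houses the excitation-channel chooser (nearest LED to the
primary excitation maximum) and the calibration-curve limit-of-detection
estimator (3.3·σ_blank / slope).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EstimationError, InsufficientDataError
from .simulate import FluorophoreSpec, LedChannel

logger = logging.getLogger(__name__)

TREND_LABELS = ("healthy_growth", "degradation", "contamination", "indeterminate")


@dataclass
class FluorSeries:
    """Timestamped fluorescence-index values with matched OD readings."""

    times_h: np.ndarray
    index_values: np.ndarray
    od_values: np.ndarray
    led_id: str = "615nm"
    fluor_band: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.index_values = np.asarray(self.index_values, dtype=float)
        self.od_values = np.asarray(self.od_values, dtype=float)
        n = len(self.times_h)
        if len(self.index_values) != n or len(self.od_values) != n:
            raise ValueError("times, index and OD must have equal lengths")
        if n > 1 and not np.all(np.diff(self.times_h) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times_h)


@dataclass
class TrendVerdict:
    """Outcome of trend classification."""

    label: str
    od_slope_sign: int
    fluor_slope_sign: int
    od_slope_per_h: float
    fluor_slope_per_h: float
    onset_h: Optional[float] = None
    confidence: float = 0.0

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "od_slope_sign": self.od_slope_sign,
            "fluor_slope_sign": self.fluor_slope_sign,
            "od_slope_per_h": self.od_slope_per_h,
            "fluor_slope_per_h": self.fluor_slope_per_h,
            "onset_h": self.onset_h,
            "confidence": self.confidence,
        }


def _normalize_to_initial(values: np.ndarray) -> np.ndarray:
    """Divide by the first finite value; non-positive start falls back to
    max-normalization with a warning."""
    values = np.asarray(values, dtype=float)
    finite = values[np.isfinite(values)]
    if len(finite) == 0:
        raise InsufficientDataError("no finite values to normalize")
    first = finite[0]
    if first > 0:
        return values / first
    peak = np.nanmax(np.abs(values))
    if peak <= 0:
        return np.ones_like(values)
    logger.warning(
        "non-positive initial value %.4g; falling back to max-normalization",
        first,
    )
    return values / peak


def normalize_series(series: FluorSeries) -> FluorSeries:
    """Series rescaled so the fluorescence index starts at 1."""
    return FluorSeries(
        times_h=series.times_h.copy(),
        index_values=_normalize_to_initial(series.index_values),
        od_values=series.od_values.copy(),
        led_id=series.led_id,
        fluor_band=series.fluor_band,
    )


def _trailing_slope(
    times: np.ndarray, values: np.ndarray, window_h: Optional[float]
) -> float:
    """Theil–Sen slope over the trailing window (``None`` = full span; a
    window holding fewer than three points expands to the last three)."""
    if window_h is None:
        window_h = times[-1] - times[0]
    sel = times >= times[-1] - window_h
    if sel.sum() < 3:
        sel = np.zeros_like(sel)
        sel[-min(3, len(times)):] = True
    t, v = times[sel], values[sel]
    if len(t) == 2:
        return float((v[1] - v[0]) / (t[1] - t[0]))
    return float(stats.theilslopes(v, t).slope)


def _sign(slope: float, threshold: float) -> int:
    if slope > threshold:
        return 1
    if slope < -threshold:
        return -1
    return 0


_SIGN_TABLE = {
    (1, 1): "healthy_growth",
    (1, -1): "contamination",
    (-1, -1): "degradation",
}


def classify_trend(
    series: FluorSeries,
    window_h: Optional[float] = None,
    slope_threshold: float = 0.01,
) -> TrendVerdict:
    """Classify the culture trend from OD and fluorescence slopes.

    Both series are normalized to their initial values (making the verdict
    invariant to positive rescaling of either), then robust Theil–Sen
    slopes over the trailing ``window_h`` hours — the full series span by
    default, since a fluorescence trace that has already collapsed to the
    blank floor carries no slope in a short trailing window — are reduced
    to signs with a ``±slope_threshold`` flat band (units: fraction of the
    initial value per hour).  ``onset_h`` is the earliest time from which
    the verdict's sign pattern holds persistently through the end of the
    series.
    """
    n = len(series)
    if n < 4:
        raise InsufficientDataError("need at least 4 points to classify a trend")
    span = series.times_h[-1] - series.times_h[0]
    if span <= 0:
        raise InsufficientDataError("series has no time span")

    od_norm = _normalize_to_initial(series.od_values)
    fl_norm = _normalize_to_initial(series.index_values)
    times = series.times_h

    od_slope = _trailing_slope(times, od_norm, window_h)
    fl_slope = _trailing_slope(times, fl_norm, window_h)
    od_sign = _sign(od_slope, slope_threshold)
    fl_sign = _sign(fl_slope, slope_threshold)
    label = _SIGN_TABLE.get((od_sign, fl_sign), "indeterminate")

    onset: Optional[float] = None
    if label != "indeterminate":
        # Walk backwards through window endpoints while the pattern persists.
        onset = times[-1]
        for k in range(n - 1, 2, -1):
            sub_t, sub_od, sub_fl = times[: k + 1], od_norm[: k + 1], fl_norm[: k + 1]
            s_od = _sign(_trailing_slope(sub_t, sub_od, window_h), slope_threshold)
            s_fl = _sign(_trailing_slope(sub_t, sub_fl, window_h), slope_threshold)
            if (s_od, s_fl) == (od_sign, fl_sign):
                onset = float(sub_t[-1])
            else:
                break

    decisive = min(abs(od_slope), abs(fl_slope))
    confidence = float(min(1.0, decisive / (2.0 * slope_threshold))) \
        if label != "indeterminate" else 0.0

    return TrendVerdict(
        label=label,
        od_slope_sign=od_sign,
        fluor_slope_sign=fl_sign,
        od_slope_per_h=od_slope,
        fluor_slope_per_h=fl_slope,
        onset_h=onset,
        confidence=confidence,
    )


def select_excitation_led(
    fluor: FluorophoreSpec, bank: Sequence[LedChannel]
) -> LedChannel:
    """Choose the excitation channel whose peak lies nearest the
    fluorophore's PRIMARY excitation maximum; ties break toward the
    shorter-wavelength LED."""
    if not bank:
        raise ValueError("LED bank is empty")
    target = fluor.primary_excitation_nm
    return min(bank, key=lambda ch: (abs(ch.peak_nm - target), ch.peak_nm))


@dataclass
class LodResult:
    """Limit of detection with calibration-fit diagnostics."""

    lod_cells_per_ul: float
    slope: float
    intercept: float
    r_squared: float
    blank_sd: float
    factor: float
    n_points: int
    n_blanks: int

    def to_dict(self) -> dict:
        return {
            "lod_cells_per_ul": self.lod_cells_per_ul,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "blank_sd": self.blank_sd,
            "factor": self.factor,
            "n_points": self.n_points,
            "n_blanks": self.n_blanks,
        }


def estimate_lod(
    calibration: Union[pd.DataFrame, Sequence[tuple[float, float]]],
    blanks: Sequence[float],
    factor: float = 3.3,
) -> LodResult:
    """Calibration-curve limit of detection.

    Fits ``index = a + b·concentration`` by ordinary least squares and
    returns ``LoD = factor · sd(blanks) / b`` (``factor`` 3.3 by
    convention; 3.0 selectable).

    Raises
    ------
    InsufficientDataError
        Fewer than 3 distinct concentrations or fewer than 3 blanks.
    EstimationError
        Fitted slope is not positive (signal does not increase with
        concentration).
    """
    if isinstance(calibration, pd.DataFrame):
        conc = calibration["concentration"].to_numpy(dtype=float)
        idx = calibration["index"].to_numpy(dtype=float)
    else:
        arr = np.asarray(calibration, dtype=float)
        conc, idx = arr[:, 0], arr[:, 1]
    blanks = np.asarray(blanks, dtype=float)
    if len(np.unique(conc)) < 3:
        raise InsufficientDataError("need >= 3 distinct concentrations")
    if len(blanks) < 3:
        raise InsufficientDataError("need >= 3 blank replicates")
    fit = stats.linregress(conc, idx)
    if not fit.slope > 0:
        raise EstimationError(
            f"calibration slope {fit.slope:.3g} is not positive"
        )
    blank_sd = float(np.std(blanks, ddof=1))
    return LodResult(
        lod_cells_per_ul=factor * blank_sd / fit.slope,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        blank_sd=blank_sd,
        factor=factor,
        n_points=len(conc),
        n_blanks=len(blanks),
    )


def empirical_lod(
    index_sampler: Callable[[float, int], np.ndarray],
    concentrations: Sequence[float],
    n_replicates: int = 200,
    n_blanks: int = 500,
    blank_quantile: float = 0.99,
    detection_power: float = 0.95,
) -> Optional[float]:
    """Brute-force empirical detection limit.

    ``index_sampler(concentration, n)`` must return ``n`` independent
    fluorescence indices at that concentration.  The detection cutoff is
    the ``blank_quantile`` of ``n_blanks`` blank indices; the empirical LoD
    is the smallest tested concentration whose index exceeds the cutoff in
    at least ``detection_power`` of replicates.  Returns ``None`` when no
    tested concentration reaches the required power.
    """
    cutoff = float(np.quantile(index_sampler(0.0, n_blanks), blank_quantile))
    for conc in sorted(c for c in concentrations if c > 0):
        detected = np.mean(index_sampler(float(conc), n_replicates) > cutoff)
        if detected >= detection_power:
            return float(conc)
    return None
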