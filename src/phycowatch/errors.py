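"""Exception hierarchy shared across the package."""


class PhycowatchError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(PhycowatchError, ValueError):
    """Invalid or inconsistent configuration."""


class BandRangeError(PhycowatchError, ValueError):
    """A wavelength band falls outside the sampled spectrum."""


class InsufficientDataError(PhycowatchError, ValueError):
    """Not enough usable samples/points for the requested operation."""


class NormalizationError(PhycowatchError, ArithmeticError):
    """The excitation-peak reference is zero or negative; the
    scattering-normalized fluorescence index is undefined."""


class SaturationError(PhycowatchError, ValueError):
    """A quantitation region is fully saturated."""


class EstimationError(PhycowatchError, ValueError):
    """A statistical estimate is undefined (e.g. non-positive slope)."""


class AcquisitionError(PhycowatchError, RuntimeError):
    """Instrument-level failure during a measurement."""


class CaptureError(AcquisitionError):
    """The spectrometer failed to deliver a spectrum."""


class SchedulingError(PhycowatchError, ValueError):
    """The monitoring schedule is infeasible (interval shorter than a round)."""


class SinkError(PhycowatchError, OSError):
    """Persistent storage failed while writing run artifacts."""
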