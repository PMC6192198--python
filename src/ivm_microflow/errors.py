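"""Exception types shared across the pipeline."""


class IvmError(Exception):
    """Base class for all package errors."""


class ConfigurationError(IvmError):
    """Invalid preset, parameter set, or run configuration."""


class GenerationError(IvmError):
    """Synthetic data could not be generated under the given parameters."""


class CalibrationError(IvmError):
    """An image lacks the calibration needed for physical units."""


class InsufficientDataError(IvmError):
    """Too few samples/frames/subjects for the requested estimate."""


class GeometryError(IvmError):
    """Vessel geometry is empty or degenerate."""


class AggregationError(IvmError):
    """A multi-ROI aggregate is missing one of its required ROIs."""


class DependencyError(IvmError):
    """A pipeline stage was requested without its upstream artifact."""
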