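"""Exception types shared across the package."""


class MvShakeError(Exception):
    """Base class for all package errors."""


class SynchronizationError(MvShakeError):
    """Frame streams that should be synchronized have different lengths."""


class ValidationError(MvShakeError):
    """An annotation or prediction file violates its contract."""


class SchedulingError(MvShakeError):
    """A requested event schedule cannot fit in the session."""


class ResolutionError(MvShakeError):
    """Requested rendering resolution is below the supported minimum."""


class DataError(MvShakeError):
    """A dataset is empty or degenerate (e.g. single-class)."""


class ParameterError(MvShakeError):
    """An operation parameter is out of its valid range."""


class ConfigurationError(MvShakeError):
    """A model is applied to data incompatible with its training configuration."""


class UndefinedMetricError(MvShakeError):
    """A metric is undefined for the given inputs (e.g. single-class ROC)."""
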