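"""Exception hierarchy shared across the package."""


class AdbsKitError(Exception):
    """Base class for all package-specific errors."""


class InvalidBandError(AdbsKitError, ValueError):
    """Filter band falls outside the representable (0, Nyquist) range."""


class InsufficientLengthError(AdbsKitError, ValueError):
    """Signal too short for the requested operation."""


class InsufficientDataError(AdbsKitError, ValueError):
    """Not enough events/levels/bursts to compute a statistic."""


class FormatError(AdbsKitError, ValueError):
    """Malformed time-series file."""


class DegenerateSignalError(AdbsKitError, ValueError):
    """Signal carries no usable structure (constant, rank-deficient, ...)."""


class StreamError(AdbsKitError, RuntimeError):
    """Inconsistent streaming state (rate mismatch, empty buffer, ...)."""


class UndefinedMetricError(AdbsKitError, ValueError):
    """Metric undefined for the given events (e.g. a leg with no strides)."""


class NoPeakError(AdbsKitError, ValueError):
    """No beta peak rises above the 1/f background."""


class NoWindowError(AdbsKitError, ValueError):
    """No stimulation amplitude satisfies the benefit rule."""
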