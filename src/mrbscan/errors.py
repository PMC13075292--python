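"""Exception hierarchy shared across the package."""


class MrbScanError(Exception):
    """Base class for all package-specific errors."""


class DomainError(MrbScanError, ValueError):
    """An argument is outside the physically or mathematically valid domain."""


class ConfigurationError(MrbScanError, ValueError):
    """A configuration (geometry, schedule, numerics) is internally inconsistent."""


class AlignmentError(MrbScanError, ValueError):
    """Two traces cannot be registered onto a common grid (e.g. different scan speeds)."""


class NoBoundaryError(MrbScanError, ValueError):
    """A trace carries no localizable boundary signature (e.g. flat signal)."""


class InsufficientDataError(MrbScanError, ValueError):
    """Fewer valid data points than the procedure requires."""


class DegenerateModelError(MrbScanError, ValueError):
    """A fitted model cannot be inverted or applied (e.g. zero slope)."""
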