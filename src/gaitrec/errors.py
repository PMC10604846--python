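"""Exception hierarchy shared across the package."""


class GaitRecError(Exception):
    """Base class for all package-specific errors."""


class SkeletonFormatError(GaitRecError):
    """Raised when a skeleton file violates the documented dialect."""


class ValidationError(GaitRecError):
    """Raised when a domain object violates one of its invariants."""


class DegenerateGeometryError(GaitRecError):
    """Raised when a limb/link vector is too short to define an angle."""

    def __init__(self, message: str, frame: int | None = None):
        super().__init__(message)
        self.frame = frame


class InsufficientGaitCyclesError(GaitRecError):
    """Raised when fewer than two gait cycles can be detected per side."""


class ConfigurationError(GaitRecError):
    """Raised for invalid model/training/simulation configuration."""
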