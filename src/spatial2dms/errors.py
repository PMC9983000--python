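"""Exception hierarchy shared across the package."""


class Spatial2DMSError(Exception):
    """Base class for all package errors."""


class DomainError(Spatial2DMSError, ValueError):
    """An argument is outside the physical/mathematical domain of an operation."""


class ConfigurationError(Spatial2DMSError, ValueError):
    """An instrument/schedule/pattern configuration is internally inconsistent."""


class ChannelLookupError(Spatial2DMSError, LookupError):
    """No detection channel matches the requested m/z within tolerance."""


class CalibrationError(Spatial2DMSError, ValueError):
    """Calibration fit/apply failure (bad points, unit or variant mismatch)."""


class DegeneratePeakError(Spatial2DMSError, ValueError):
    """A picked peak has no measurable width."""


class GenerationError(Spatial2DMSError, RuntimeError):
    """The synthetic-mixture generator could not satisfy its constraints."""


class ParseError(Spatial2DMSError, ValueError):
    """A configuration or data file could not be parsed."""
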