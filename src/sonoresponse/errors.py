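"""Exception hierarchy shared across the package."""


class SonoresponseError(Exception):
    """Base class for all package-specific errors."""


class InvalidSequenceError(SonoresponseError, ValueError):
    """An ultrasound pulse sequence violates its parametric invariants."""


class MissingParameterError(SonoresponseError, ValueError):
    """A computation requires a parameter that was not supplied."""


class ResolutionError(SonoresponseError, ValueError):
    """A sample rate is too low to resolve the requested structure."""


class InsufficientBaselineError(SonoresponseError, ValueError):
    """No frames available in the pre-stimulus baseline window."""


class DegenerateBaselineError(SonoresponseError, ValueError):
    """Baseline fluorescence is non-positive; dF/F0 is undefined."""


class InsufficientResponseWindowError(SonoresponseError, ValueError):
    """The post-stimulus response window is truncated by the recording."""


class OverlappingWindowsError(SonoresponseError, ValueError):
    """Analysis windows of consecutive stimuli overlap."""


class DegenerateSignalError(SonoresponseError, ValueError):
    """The voltage trace has zero estimated noise scale."""


class DegenerateTableError(SonoresponseError, ValueError):
    """A contingency table has a zero marginal."""


class MissingDataError(SonoresponseError, ValueError):
    """A requested group contains no data."""


class GeometryMismatchError(SonoresponseError, ValueError):
    """Two binned objects do not share the same bin geometry."""


class ParseError(SonoresponseError, ValueError):
    """A text input file could not be parsed."""


class ConfigError(SonoresponseError, ValueError):
    """An analysis configuration violates its invariants."""
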