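"""Exception hierarchy.

``EntraceError`` subclasses ``ValueError`` so callers that only know the
standard library still catch parameter problems naturally.
"""


class EntraceError(ValueError):
    """Base class for all package-specific errors."""


class ParameterError(EntraceError):
    """A configuration or parameter value is invalid."""


class ConfigError(ParameterError):
    """A pipeline configuration file failed validation.

    ``field`` names the offending entry so command-line users can fix it.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"config field '{field}': {message}")


class EmptyFieldError(EntraceError):
    """A field with zero cells was requested or encountered."""


class LayoutError(EntraceError):
    """Cell footprints cannot be placed on the requested canvas."""


class DecompositionError(EntraceError):
    """The slow/fast separation is not well defined for this trace."""


class ClassificationError(EntraceError):
    """Per-field classification cannot be computed (e.g. fewer than 2 cells)."""


class NormalizationError(EntraceError):
    """A dose-response component cannot be max-normalized (zero maximum)."""
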