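"""Exception hierarchy used across the package."""


class AefnError(Exception):
    """Base class for all package-specific errors."""


class FormatError(AefnError):
    """A file or cell does not conform to the expected text format."""


class ValidationError(AefnError):
    """Parsed data violates a structural invariant (shape, range, finiteness)."""


class AlignmentError(AefnError):
    """Two tables that must share row order/length do not."""


class InputError(AefnError):
    """An argument is outside its documented domain."""


class ConfigError(AefnError):
    """A simulation or run configuration is inconsistent."""


class DegenerateDataError(AefnError):
    """Data cannot support the requested model (e.g. zero-variance features)."""


class UndefinedMetricError(AefnError):
    """A metric is undefined for the given inputs (e.g. single-class truth)."""
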