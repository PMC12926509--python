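"""Exception hierarchy shared across the package."""


class ChpSilkError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ChpSilkError):
    """A file could not be parsed into the expected schema."""


class IntegrityError(ChpSilkError):
    """Parsed data violate a structural invariant (e.g. duplicate keys)."""


class ValidationError(ChpSilkError):
    """A value is outside its permitted domain."""


class InsufficientDataError(ChpSilkError):
    """Too few points to perform the requested estimate."""


class UndefinedRatioError(ValidationError):
    """A tracer-to-tracee ratio was requested with a nonpositive denominator."""


class ConfigError(ChpSilkError):
    """Invalid run or scenario configuration."""
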