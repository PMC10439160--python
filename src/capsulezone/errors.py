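"""Exception hierarchy shared across the package."""


class CapsulezoneError(Exception):
    """Base class for all package errors."""


class ValidationError(CapsulezoneError):
    """An input violates a documented precondition or schema."""


class AnnotationParseError(ValidationError):
    """An annotation file could not be parsed into the documented schema."""


class NoInterfaceError(ValidationError):
    """A slide has no interface segments and cannot be scored."""


class ConvergenceError(CapsulezoneError):
    """A model fit failed to converge (e.g. monotone Cox partial likelihood)."""
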