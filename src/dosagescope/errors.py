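"""Exception hierarchy shared across the package."""


class DosagescopeError(Exception):
    """Base class for all package errors."""


class CoordinateError(DosagescopeError, ValueError):
    """A coordinate lies outside the chromosome's [0, L) range."""


class FormatError(DosagescopeError, ValueError):
    """An input file violates its format contract."""


class InputError(DosagescopeError, ValueError):
    """Inputs are individually well-formed but mutually inconsistent or unusable."""


class ConfigError(DosagescopeError, ValueError):
    """A configuration value is missing, unknown, or out of range."""


class DegenerateFitError(DosagescopeError, RuntimeError):
    """A model fit has no usable solution (e.g. parallel regression lines)."""


class DomainError(DosagescopeError, ValueError):
    """A value is outside the mathematical domain of an operation."""
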