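"""Exception types shared across the package."""


class ImmunogateError(Exception):
    """Base class for all package errors."""


class FormatError(ImmunogateError, ValueError):
    """An on-disk input does not conform to its expected layout."""


class ValidationError(ImmunogateError, ValueError):
    """In-memory data violate an invariant or precondition."""


class ConfigError(ImmunogateError, ValueError):
    """A configuration object is internally inconsistent or degenerate."""
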