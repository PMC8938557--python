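"""Exception hierarchy shared across the package."""


class AffectBanditError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(AffectBanditError, ValueError):
    """A configuration object violates one of its invariants."""


class DomainError(AffectBanditError, ValueError):
    """A numeric argument lies outside its mathematical domain."""


class DataError(AffectBanditError, ValueError):
    """Input data are malformed (ordering, schema, or value constraints)."""


class UndefinedCorrelationError(DataError):
    """A correlation is undefined (zero variance in an input)."""
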