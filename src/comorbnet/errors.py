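"""Exception hierarchy shared across the package."""


class ComorbnetError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(ComorbnetError):
    """A delimited-text input is missing required columns."""


class ValidationError(ComorbnetError):
    """Input rows violate a domain invariant (age floor, non-binary cells...)."""


class ConfigError(ComorbnetError):
    """A generator or pipeline configuration is invalid."""


class DomainError(ComorbnetError):
    """An operation was called outside its mathematical domain."""
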