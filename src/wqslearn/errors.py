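"""Exception hierarchy shared across the package."""


class WqslearnError(Exception):
    """Base class for package errors."""


class ConfigurationError(WqslearnError, ValueError):
    """Invalid generator or pipeline configuration."""


class ValidationError(WqslearnError, ValueError):
    """Input data violates a documented precondition."""


class SchemaError(WqslearnError, ValueError):
    """A table does not conform to its declared schema."""


class FitError(WqslearnError, RuntimeError):
    """A model fit failed to converge or was handed degenerate data."""
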