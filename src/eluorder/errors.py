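"""Exception hierarchy shared across the package."""


class EluorderError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(EluorderError):
    """A required column or field is missing from an input."""


class ValidationError(EluorderError):
    """Input data violates an invariant (non-finite descriptor, t_R <= 0, ...)."""


class ConfigurationError(EluorderError):
    """A configuration value violates its allowed range."""


class SingularDesignError(EluorderError):
    """The regression design matrix is rank deficient."""
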