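"""Exception types shared across the package."""


class NPSubstituteError(Exception):
    """Base class for all package errors."""


class SchemaError(NPSubstituteError):
    """A delimited input file is missing required columns or carries
    columns inconsistent with its declared source."""


class IntegrityError(NPSubstituteError):
    """Referential problems: duplicate IDs, orphan IDs in match tables."""


class ValidationError(NPSubstituteError):
    """A value violates a domain invariant (negative nutrient,
    non-positive reference amount, cross-category match pair, ...)."""


class ConfigError(NPSubstituteError):
    """A run or generator configuration is incomplete or inconsistent."""
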