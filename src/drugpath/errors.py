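"""Exception hierarchy shared across the package."""


class DrugPathError(Exception):
    """Base class for all package-specific errors."""


class ParseError(DrugPathError):
    """A text input could not be parsed; the message names the offending line."""


class ValidationError(DrugPathError):
    """A parsed object violates a structural invariant."""


class DrugExcludedError(DrugPathError):
    """A drug lacks at least one gene in one of the five seed categories.

    Mirrors the admission filter applied before pathway construction: only
    drugs with a non-empty target, variant, expression, disease and
    side-effect gene set are eligible.
    """


class ConfigurationError(DrugPathError):
    """A configuration value is outside its documented range."""


class UntestableThresholdError(DrugPathError):
    """No candidate pairs exist at a similarity threshold, so the enrichment
    test for that threshold cannot be performed."""
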