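"""Exception hierarchy for harmonization errors."""


class HarmonizationError(ValueError):
    """Base class for all errors raised by combatpredict."""


class DataValidationError(HarmonizationError):
    """Input data violates a structural requirement (missing values, shape
    mismatch, unknown column, site below the minimum size, ...)."""


class RankDeficientDesignError(HarmonizationError):
    """The standardization design is rank deficient, typically because a
    covariate is confounded with the site indicators."""


class DegenerateFeatureError(HarmonizationError):
    """A feature has zero pooled residual variance and cannot be standardized."""


class DegeneratePriorError(HarmonizationError):
    """Across-feature moments do not identify the site hyperprior
    (e.g. zero variance of the delta^2 estimates)."""


class DegeneratePosteriorError(HarmonizationError):
    """The inverse-gamma posterior-mean denominator n/2 + lambda - 1 is not
    positive; the empirical-Bayes update is undefined."""


class SchemaError(HarmonizationError):
    """A serialized fit does not conform to the expected JSON schema."""
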