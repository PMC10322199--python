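"""Exception hierarchy shared across the package."""


class SwevowelError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(SwevowelError):
    """A required column is missing or the schema mapping is unusable."""


class ParseError(SwevowelError):
    """A cell could not be parsed as the expected type."""


class ValidationError(SwevowelError):
    """Token data violates a structural invariant (positivity, formant order,
    duplicate identifiers, unknown vowel labels)."""


class ConfigError(SwevowelError):
    """An account/cue-set combination or a parameter value is invalid."""


class FitError(SwevowelError):
    """Parameter fitting failed (too few tokens, singular covariance)."""


class DegenerateStatsError(FitError):
    """A talker statistic needed by an account is degenerate
    (zero variance for a z-score, zero range for range normalization)."""
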