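"""Exception hierarchy shared across the package.

Every error raised by ccekit derives from :class:`CCEError`, so callers
(and the CLI) can distinguish data/contract violations from programming
errors with a single ``except``.
"""


class CCEError(ValueError):
    """Base class for all ccekit data and configuration errors."""


class InvalidSampleError(CCEError):
    """A response sample violates its contract (e.g. zero respondents)."""


class DegenerateScaleError(CCEError):
    """A rank scale has zero width or fewer than two ranks."""


class InvalidReferenceError(CCEError):
    """A reference rank is not a member of the scale."""


class InvalidQuantityError(CCEError):
    """A respondent count is negative."""


class SchemaError(CCEError):
    """A vector schema is inconsistent or an input does not conform to it."""


class FormatError(CCEError):
    """A serialized artifact does not match its declared layout."""


class ConfigError(CCEError):
    """An option value (metric name, k, weights) is out of range or unknown."""


class InvalidInputError(CCEError):
    """An operation received an empty or otherwise unusable input."""


class SingularCovarianceError(CCEError):
    """A covariance matrix is singular and regularization is disabled."""


class UndefinedAngleError(CCEError):
    """Cosine distance requested against a zero vector."""


class InvalidScenarioError(CCEError):
    """A synthetic-data scenario violates its contract."""
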