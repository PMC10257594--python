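"""Exception hierarchy shared across the toolkit."""


class FaceNormsError(Exception):
    """Base class for all toolkit errors."""


class ConfigurationError(FaceNormsError, ValueError):
    """A cohort or run configuration is internally inconsistent."""


class ValidationError(FaceNormsError, ValueError):
    """An input value violates a documented contract (range, schema, shape)."""


class SchemaError(ValidationError):
    """A file is missing required columns/fields or has an incompatible version."""


class DomainError(FaceNormsError, ValueError):
    """A value lies outside the mathematical domain of a transform."""


class FitError(FaceNormsError, ValueError):
    """A regression cannot be estimated (too few rows, rank deficiency)."""


class SampleTooSmallError(FaceNormsError, ValueError):
    """No order statistic satisfies the tolerance-limit criterion at this n."""

    def __init__(self, message: str, minimal_n: int | None = None):
        super().__init__(message)
        self.minimal_n = minimal_n


class DegenerateDistributionError(FaceNormsError, ValueError):
    """A sample with no spread (or a perfectly collinear covariate) was supplied."""
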