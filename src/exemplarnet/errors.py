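"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: usage errors exit 2 (handled by click),
validation/configuration errors exit 3, numerical errors exit 4.
"""


class ExemplarNetError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(ExemplarNetError):
    """A config/dialect problem detected before any computation (e.g. a
    missing required column)."""

    exit_code = 3


class ValidationError(ExemplarNetError):
    """Input data violates a documented precondition."""

    exit_code = 3


class PipelineError(ExemplarNetError):
    """A pipeline stage cannot proceed (e.g. fewer than two genes left to
    cluster after the degree filter)."""

    exit_code = 3


class NumericalError(ExemplarNetError):
    """Non-finite values encountered during message passing."""

    exit_code = 4


class UndefinedSimilarityError(ValidationError):
    """Neighborhood similarity requested for a gene with no interaction
    partners; callers must exclude degree-0 genes first."""
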