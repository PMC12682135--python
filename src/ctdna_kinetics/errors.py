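"""Exception hierarchy for the ctDNA analysis pipeline.

``DataError`` covers malformed or inconsistent *input* (exit code 1 in the
CLI); ``UsageError`` covers caller mistakes (exit code 2).
"""


class CtdnaError(Exception):
    """Base class for all package exceptions."""


class DataError(CtdnaError, ValueError):
    """Input data violates a contract (bad counts, dates, schema ...)."""


class UsageError(CtdnaError, ValueError):
    """The caller invoked an operation incorrectly."""


class SaturatedWellError(DataError):
    """Every droplet positive: concentration not estimable; dilute upstream."""


class EmptyWellError(DataError):
    """A well with zero accepted droplets."""


class InconsistentWellsError(DataError):
    """Wells merged across different samples, assays or droplet volumes."""


class NoTemplateError(DataError):
    """Neither mutant nor wild-type target present: sample not evaluable."""


class OrderingError(DataError):
    """Longitudinal samples out of time order."""


class NotEvaluableError(DataError):
    """Patient lacks the sample required for the requested status call."""


class SchemaError(DataError):
    """A CSV input does not match the expected schema."""


class DependencyError(DataError):
    """A pipeline stage is missing an upstream artifact."""
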