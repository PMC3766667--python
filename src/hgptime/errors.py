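"""Exception types shared across the package."""


class StructureError(ValueError):
    """Raised when data and hierarchy specification are structurally incompatible."""


class SchemaError(ValueError):
    """Raised when an input table is missing columns or contains unparseable rows."""


class NumericalError(RuntimeError):
    """Raised when a covariance matrix cannot be factorized even after jitter.

    The message carries the smallest eigenvalue of the offending matrix.
    """


class SharedGridError(ValueError):
    """Signals that the efficient cluster-likelihood path is invalid.

    Raised when the genes of a cluster do not share an identical
    (replicate, time) measurement layout; callers fall back to the
    naive likelihood.
    """


class BaselineInapplicableError(ValueError):
    """Raised when a replicate-averaging baseline has no replicate sharing the target time."""


class UndefinedStatisticError(ValueError):
    """Raised when a summary statistic is undefined (e.g. BHI with no within-cluster pairs)."""


class NoInformationError(ValueError):
    """Raised when imputation is requested for a gene absent from the training data."""
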