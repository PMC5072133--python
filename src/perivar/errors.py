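"""Exception hierarchy shared across the pipeline stages."""


class PerivarError(Exception):
    """Base class for all package errors."""


class ValidationError(PerivarError):
    """Malformed or out-of-range input (tables, parameters, config)."""


class BalanceError(ValidationError):
    """Slide count incompatible with the 3x3 factorial balance."""


class InsufficientReplicatesError(PerivarError):
    """Fewer than two replicate slides available for a statistic."""


class UndefinedCVError(PerivarError):
    """Coefficient of variation requested for a zero-mean population."""


class SelectionError(PerivarError):
    """Taxon selection asked for more taxa than the table contains."""


class DesignMatrixError(PerivarError):
    """Invalid treatment code or rank-deficient factorial design matrix."""


class DegenerateHullError(PerivarError):
    """Convex hull of fewer than 3 points, or of collinear points."""

    def __init__(self, message: str, points=None):
        super().__init__(message)
        self.points = points


class FitError(PerivarError):
    """A model fit failed irrecoverably."""
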