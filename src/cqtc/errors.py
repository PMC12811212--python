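"""Exception hierarchy for the C-QTc analysis pipeline."""


class CqtcError(Exception):
    """Base class for all pipeline errors."""


class InvalidMeasurementError(CqtcError):
    """A raw ECG measurement violates its physical constraints (e.g. QT <= 0)."""


class MissingTimepointError(CqtcError):
    """No replicate measurements exist where at least one is required."""


class BaselineMissingError(CqtcError):
    """A (subject, period) lacks the Day-1 pre-dose point that defines its baseline."""


class ConfigurationError(CqtcError):
    """Bad or inconsistent run configuration (unknown unit label, missing inputs...)."""


class DataError(CqtcError):
    """Input data violate a contract (negative concentration, inconsistent RR/HR...)."""


class IntegrityError(CqtcError):
    """Duplicate or conflicting keys detected during dataset assembly."""


class DesignMatrixError(CqtcError):
    """The analysis table cannot be coded into the model's design matrix."""


class RankError(DesignMatrixError):
    """The fixed-effects design matrix is rank deficient."""


class ConvergenceFailure(CqtcError):
    """ML optimisation did not meet the convergence criteria.

    Carries the best iterate found so that the simplification ladder can
    inspect (and report) it.
    """

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class ModelFitError(CqtcError):
    """Terminal model failure: every rung of the simplification ladder failed."""


class DiagnosticsError(CqtcError):
    """A diagnostic statistic cannot be computed from the data provided."""
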