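"""Exception hierarchy shared across the pipeline.

Errors are split into *design* problems (an experiment or request that can
never be valid, e.g. a one-level calibration), *data* problems (a table that
violates its schema or physical constraints) and *statistical degeneracy*
(inputs that are structurally fine but leave the requested quantity
undefined, e.g. zero-variance ANOVA groups or a detection curve that never
crosses the threshold criterion).
"""


class PyrasenseError(Exception):
    """Base class for all package errors."""


class DesignError(PyrasenseError):
    """The requested design/experiment is invalid (e.g. dilution factor <= 1)."""


class DataError(PyrasenseError):
    """Input data violate a schema or physical constraint."""


class InsufficientDataError(DataError):
    """Too few observations to compute the requested quantity."""


class DegenerateModelError(PyrasenseError):
    """A fitted or supplied model cannot be used (e.g. zero calibration slope)."""


class DegenerateVarianceError(PyrasenseError):
    """Zero within-group variance makes the test statistic undefined."""


class NoCrossingError(PyrasenseError):
    """A detection curve never reaches the threshold criterion.

    Carries ``max_proportion``, the largest observed (smoothed) proportion,
    so callers can report how far short the curve fell.
    """

    def __init__(self, message: str, max_proportion: float | None = None):
        super().__init__(message)
        self.max_proportion = max_proportion


class FitError(PyrasenseError):
    """A maximum-likelihood fit is non-identifiable or failed to converge."""
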