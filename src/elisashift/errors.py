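"""Exception hierarchy for elisashift.

All package errors derive from :class:`ElisaShiftError` so callers (and the
CLI) can catch one base class and translate to a nonzero exit status.
"""

from __future__ import annotations


class ElisaShiftError(Exception):
    """Base class for all elisashift errors."""


class FormatError(ElisaShiftError):
    """A file does not conform to the expected dialect (missing column, bad value)."""


class DuplicateWellError(FormatError):
    """The same (plate_id, well) address appears more than once."""


class DataError(ElisaShiftError):
    """Input data violate a precondition (too few standard levels, NaN reading, ...)."""


class DegenerateDataError(DataError):
    """Data carry no usable signal (e.g. all optical densities identical)."""


class ConvergenceError(ElisaShiftError):
    """The optimizer failed to converge; carries the best attempt found."""

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


class RangeError(ElisaShiftError):
    """An OD lies outside the open interval between the curve asymptotes.

    ``tag`` is ``"below_range"`` (low-concentration side) or ``"above_range"``.
    """

    def __init__(self, message: str, tag: str):
        super().__init__(message)
        self.tag = tag


class UnknownBatchError(ElisaShiftError, KeyError):
    """A batch label is not present in the fitted shift model."""


class UndefinedCVError(ElisaShiftError):
    """Coefficient of variation undefined (mean is zero or negative)."""


class UndefinedFoldError(ElisaShiftError):
    """Fold ratio undefined (group mean is zero); carries the absolute difference."""

    def __init__(self, message: str, abs_difference: float):
        super().__init__(message)
        self.abs_difference = abs_difference


class ValidationError(ElisaShiftError):
    """A specification object (simulation spec, run config) is invalid."""
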