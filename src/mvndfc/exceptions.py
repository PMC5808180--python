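"""Exception hierarchy for the mvndfc package.

Every error raised by the library derives from :class:`MvndfcError`, so
callers (and the CLI) can distinguish library failures from programming
errors and map them to stable exit codes.
"""

from __future__ import annotations


class MvndfcError(Exception):
    """Base class for all mvndfc errors."""


class ZeroVarianceColumn(MvndfcError):
    """An ROI time series is constant, so it cannot be standardized.

    Attributes
    ----------
    roi_index : int
        0-based column index of the offending ROI.
    window_index : int or None
        0-based window index when the failure occurred inside a sliding
        window, else None.
    """

    def __init__(self, roi_index: int, window_index: int | None = None):
        self.roi_index = roi_index
        self.window_index = window_index
        where = f" in window {window_index}" if window_index is not None else ""
        super().__init__(
            f"ROI column {roi_index} has zero variance{where}; "
            "Pearson correlation is undefined"
        )


class InvalidWindowConfig(MvndfcError):
    """Sliding-window parameters are inconsistent with the series length."""


class ShapeMismatch(MvndfcError):
    """Matrices in an operation do not share a common shape."""


class EmptySampleList(MvndfcError):
    """An estimator was called with zero sample networks."""


class SingularOmega(MvndfcError):
    """The edge-covariance factor is numerically singular.

    Attributes
    ----------
    cond : float
        Estimated condition number (inf when a Cholesky factorization
        failed outright).
    """

    def __init__(self, message: str, cond: float = float("inf")):
        self.cond = cond
        super().__init__(f"{message} (condition estimate {cond:.3g})")


class NonPositiveDefiniteOmega(MvndfcError):
    """A covariance factor that must be positive definite is not."""


class NonPositiveDiagonal(MvndfcError):
    """A covariance matrix has a non-positive diagonal entry.

    Attributes
    ----------
    index : int
        0-based index of the offending diagonal entry.
    """

    def __init__(self, index: int, value: float):
        self.index = index
        super().__init__(
            f"diagonal entry {index} is {value:.6g}; must be strictly positive "
            "to normalize to a correlation matrix"
        )


class InsufficientWindows(MvndfcError):
    """Fewer than two sliding windows: the covariance MLE is undefined."""


class InvalidFraction(MvndfcError):
    """A proportional-threshold fraction is outside (0, 1]."""


class DegenerateClass(MvndfcError):
    """A class has fewer than two samples; the t-test is undefined."""


class UndefinedMetric(MvndfcError):
    """A confusion-matrix metric has a zero denominator."""


class InvalidCorrelationTarget(MvndfcError):
    """A perturbed matrix could not be projected back to a correlation matrix."""


class ParseError(MvndfcError):
    """A delimited text file contains a malformed or non-numeric cell.

    Attributes
    ----------
    row, col : int or None
        1-based file coordinates of the offending cell when known.
    """

    def __init__(self, message: str, row: int | None = None, col: int | None = None):
        self.row = row
        self.col = col
        super().__init__(message)


class RaggedRows(ParseError):
    """Rows of a delimited text file have inconsistent lengths."""
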