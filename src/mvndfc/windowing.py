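"""ROI time series, sliding windows, and Pearson connectivity networks.

The functional connectivity (FC) pipeline starts from one subject's BOLD
signal matrix ``X`` of shape V×P (V image volumes, P regions of interest).
Each column is centered and scaled to unit Euclidean norm, so the Pearson
correlation network is simply ``X_std.T @ X_std``.  Sliding windows of
width N, advanced by a step of s volumes, cut the series into
``K = floor((V - N)/s) + 1`` overlapping subseries; the per-window
correlation networks are the samples fed to the matrix-variate normal
estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidWindowConfig, ZeroVarianceColumn

__all__ = [
    "TimeSeriesMatrix",
    "WindowConfig",
    "ConnectivityMatrix",
    "CONNECTIVITY_KINDS",
    "standardize_columns",
    "count_windows",
    "extract_windows",
    "pearson_network",
    "window_network_series",
]

#: Admissible values for :attr:`ConnectivityMatrix.kind`.
CONNECTIVITY_KINDS = ("pc", "window_pc", "low_order_M", "high_order_Omega", "fused")

_SYMMETRY_TOL = 1e-10
_DIAG_TOL = 1e-8


@dataclass
class TimeSeriesMatrix:
    """One subject's V×P ROI signal matrix.

    Parameters
    ----------
    values
        Real matrix with rows = volumes (time points) and columns = ROIs.
        Requires V >= 2, P >= 2 and finite entries.
    roi_names
        Optional P region labels carried through windowing and written as
        the header of output matrices.
    """

    values: np.ndarray
    roi_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"expected a 2-D V×P matrix, got ndim={self.values.ndim}")
        v, p = self.values.shape
        if v < 2 or p < 2:
            raise ValueError(f"need at least 2 volumes and 2 ROIs, got shape {v}×{p}")
        if not np.isfinite(self.values).all():
            raise ValueError("time series contains non-finite entries")
        if self.roi_names is not None:
            self.roi_names = tuple(str(n) for n in self.roi_names)
            if len(self.roi_names) != p:
                raise ValueError(
                    f"{len(self.roi_names)} ROI names for {p} columns"
                )

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window layout: width (N volumes) and step (s volumes)."""

    width: int
    step: int

    def __post_init__(self) -> None:
        if int(self.width) != self.width or int(self.step) != self.step:
            raise InvalidWindowConfig("window width and step must be integers")
        if self.width < 2:
            raise InvalidWindowConfig(f"window width must be >= 2, got {self.width}")
        if self.step < 1:
            raise InvalidWindowConfig(f"window step must be >= 1, got {self.step}")

    def validate_for(self, n_volumes: int) -> None:
        if self.width > n_volumes:
            raise InvalidWindowConfig(
                f"window width {self.width} exceeds series length {n_volumes}"
            )


@dataclass
class ConnectivityMatrix:
    """P×P symmetric edge-weight matrix of one network.

    ``kind`` records the stage that produced the matrix: ``pc`` (full-series
    Pearson), ``window_pc`` (per-window Pearson sample), ``low_order_M``
    (matrix-normal mean), ``high_order_Omega`` (correlation-normalized
    edge-covariance factor) or ``fused``.  All kinds carry a unit diagonal
    and entries in [-1, 1].
    """

    values: np.ndarray
    kind: str = "pc"
    roi_names: tuple[str, ...] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in CONNECTIVITY_KINDS:
            raise ValueError(f"unknown connectivity kind {self.kind!r}")
        p, q = (self.values.shape + (0, 0))[:2]
        if self.values.ndim != 2 or p != q or p < 2:
            raise ValueError(f"expected a square P×P matrix (P>=2), got {self.values.shape}")
        if not np.isfinite(self.values).all():
            raise ValueError("connectivity matrix contains non-finite entries")
        asym = np.abs(self.values - self.values.T).max()
        if asym > _SYMMETRY_TOL:
            raise ValueError(f"matrix is asymmetric (max |W - W.T| = {asym:.3g})")
        if np.abs(np.diag(self.values) - 1.0).max() > _DIAG_TOL:
            raise ValueError(f"kind {self.kind!r} requires a unit diagonal")
        if np.abs(self.values).max() > 1.0 + _DIAG_TOL:
            raise ValueError(f"kind {self.kind!r} requires entries in [-1, 1]")
        if self.roi_names is not None:
            self.roi_names = tuple(str(n) for n in self.roi_names)
            if len(self.roi_names) != p:
                raise ValueError(f"{len(self.roi_names)} ROI names for {p} nodes")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


def _standardized_values(
    x: np.ndarray, on_degenerate: str = "error", window_index: int | None = None
) -> np.ndarray:
    """Center columns and scale each to unit Euclidean norm.

    ``on_degenerate='zero'`` maps constant columns to all-zero columns
    (their correlations with every other ROI become 0) instead of raising.
    """
    if on_degenerate not in ("error", "zero"):
        raise ValueError(f"on_degenerate must be 'error' or 'zero', got {on_degenerate!r}")
    centered = x - x.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(centered, axis=0)
    # Relative floor: a column is "constant" when its centered norm is at
    # rounding level for its magnitude.
    floor = 1e-12 * np.maximum(1.0, np.abs(x).max(axis=0))
    degenerate = norms <= floor
    if degenerate.any():
        if on_degenerate == "error":
            raise ZeroVarianceColumn(int(np.flatnonzero(degenerate)[0]), window_index)
        norms = np.where(degenerate, 1.0, norms)
        centered[:, degenerate] = 0.0
    return centered / norms


def standardize_columns(
    x: TimeSeriesMatrix, on_degenerate: str = "error"
) -> TimeSeriesMatrix:
    """Center each ROI column and scale it to unit Euclidean norm.

    After standardization the Pearson network is the plain Gram matrix
    ``X.T @ X``.  Raises :class:`ZeroVarianceColumn` for constant columns
    unless ``on_degenerate='zero'``.
    """
    return TimeSeriesMatrix(
        _standardized_values(x.values, on_degenerate), roi_names=x.roi_names
    )


def count_windows(n_volumes: int, cfg: WindowConfig) -> int:
    """Number of sliding windows: ``K = floor((V - N)/s) + 1``.

    Trailing volumes that do not fill a complete window are discarded,
    which is what the floor guarantees.
    """
    cfg.validate_for(n_volumes)
    return (n_volumes - cfg.width) // cfg.step + 1


def extract_windows(x: TimeSeriesMatrix, cfg: WindowConfig) -> list[TimeSeriesMatrix]:
    """Cut the series into K overlapping width-N blocks, step s apart.

    Window k (0-based) covers rows ``k*s`` to ``k*s + N - 1`` inclusive.
    """
    k = count_windows(x.n_volumes, cfg)
    return [
        TimeSeriesMatrix(
            x.values[i * cfg.step : i * cfg.step + cfg.width].copy(),
            roi_names=x.roi_names,
        )
        for i in range(k)
    ]


def _gram_network(std_values: np.ndarray) -> np.ndarray:
    w = std_values.T @ std_values
    w = 0.5 * (w + w.T)
    np.clip(w, -1.0, 1.0, out=w)
    np.fill_diagonal(w, 1.0)
    return w


def pearson_network(
    x: TimeSeriesMatrix, kind: str = "pc", on_degenerate: str = "error"
) -> ConnectivityMatrix:
    """Pairwise Pearson correlation network of the full series.

    Equivalent to the matrix form ``X_std.T @ X_std`` with columns centered
    and normalized.  Correlations are clamped to [-1, 1] and the diagonal
    set to exactly 1 to absorb floating-point rounding.
    """
    std = _standardized_values(x.values, on_degenerate)
    return ConnectivityMatrix(_gram_network(std), kind=kind, roi_names=x.roi_names)


def window_network_series(
    x: TimeSeriesMatrix, cfg: WindowConfig, on_degenerate: str = "error"
) -> list[ConnectivityMatrix]:
    """Per-window Pearson networks ``W^(k)``, the matrix-normal samples.

    Standardization is re-done inside each window (each subseries is
    re-centered and re-normalized), so every ``W^(k)`` is itself a valid
    correlation matrix.  A constant ROI inside a window raises
    :class:`ZeroVarianceColumn` carrying both the window and ROI index.
    """
    nets = []
    for i, win in enumerate(extract_windows(x, cfg)):
        std = _standardized_values(win.values, on_degenerate, window_index=i)
        nets.append(
            ConnectivityMatrix(_gram_network(std), kind="window_pc", roi_names=x.roi_names)
        )
    return nets
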