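"""Network post-processing: fusion, proportional thresholding, vectorization.

The classification stage works on edge-weight feature vectors.  Each
subject's network is optionally fused (simple average of the low- and
high-order networks), proportionally thresholded to a target edge density,
and flattened to its upper triangle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidFraction, ShapeMismatch
from .windowing import ConnectivityMatrix

__all__ = [
    "FeatureVector",
    "fuse_networks",
    "threshold_proportional",
    "vectorize_upper",
    "devectorize_upper",
]


@dataclass
class FeatureVector:
    """Upper-triangle edge weights of one network, row-major order.

    ``edge_index[e] = (i, j)`` with ``i < j`` (0-based) gives the node pair
    of feature ``e``; the length is exactly P·(P−1)/2.
    """

    values: np.ndarray
    edge_index: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.edge_index) != self.values.size:
            raise ValueError("feature vector and edge index lengths differ")


def fuse_networks(m: ConnectivityMatrix, omega: ConnectivityMatrix) -> ConnectivityMatrix:
    """Fuse low- and high-order networks by the fixed blend 0.5·(M + Omega)."""
    if m.values.shape != omega.values.shape:
        raise ShapeMismatch(
            f"cannot fuse networks of shapes {m.values.shape} and {omega.values.shape}"
        )
    return ConnectivityMatrix(
        0.5 * (m.values + omega.values), kind="fused", roi_names=m.roi_names
    )


def threshold_proportional(
    w: ConnectivityMatrix, keep_fraction: float
) -> ConnectivityMatrix:
    """Keep the strongest ``keep_fraction`` of edges, zero the rest.

    Of the E = P·(P−1)/2 upper-triangle edges, the ``m = ceil(f·E)`` of
    largest absolute weight survive (a keep fraction of 10% filters out the
    90% weakest edges).  "Weak" means small magnitude, so strong negative
    correlations survive.  Ties keep the edge earlier in row-major order.
    The diagonal is untouched and ``keep_fraction = 1`` returns the network
    unchanged.
    """
    if not 0.0 < keep_fraction <= 1.0:
        raise InvalidFraction(f"keep_fraction must be in (0, 1], got {keep_fraction}")
    p = w.n_rois
    iu = np.triu_indices(p, k=1)
    weights = w.values[iu]
    n_edges = weights.size
    m = math.ceil(keep_fraction * n_edges)
    # Stable sort on -|w|: equal magnitudes keep row-major (earlier) edges.
    keep = np.argsort(-np.abs(weights), kind="stable")[:m]
    kept = np.zeros(n_edges)
    kept[keep] = weights[keep]
    out = np.zeros_like(w.values)
    out[iu] = kept
    out += out.T
    np.fill_diagonal(out, np.diag(w.values))
    return ConnectivityMatrix(out, kind=w.kind, roi_names=w.roi_names)


def vectorize_upper(w: ConnectivityMatrix) -> FeatureVector:
    """Flatten the strict upper triangle row-major into a feature vector."""
    p = w.n_rois
    iu = np.triu_indices(p, k=1)
    return FeatureVector(
        values=w.values[iu].copy(),
        edge_index=list(zip(iu[0].tolist(), iu[1].tolist())),
    )


def devectorize_upper(values: np.ndarray, diagonal: float = 1.0) -> np.ndarray:
    """Rebuild the symmetric P×P matrix from row-major upper-triangle values.

    The diagonal is not represented in the vector; it is filled with
    ``diagonal``.
    """
    values = np.asarray(values, dtype=float)
    n_edges = values.size
    p = round(0.5 * (1 + math.sqrt(1 + 8 * n_edges)))
    if p * (p - 1) // 2 != n_edges:
        raise ValueError(f"{n_edges} values is not a P·(P−1)/2 edge count")
    out = np.zeros((p, p))
    out[np.triu_indices(p, k=1)] = values
    out += out.T
    np.fill_diagonal(out, diagonal)
    return out
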