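"""Maximum-likelihood estimation of the matrix-variate normal FC model.

The model treats each windowed correlation network ``W^(k)`` as a draw from
a matrix-variate normal distribution ``W ~ N(M, Omega ⊗ Omega)``: the mean
``M`` is the low-order (node-node) FC network, while the covariance factor
``Omega`` encodes high-order (edge-edge) structure.  Assuming a common row
and column factor is what makes the P²×P² edge covariance tractable — its
free parameter count drops from P²(P²−1)/2 to P(P−1)/2.

The MLE of ``M`` is the sample mean.  The MLE of ``Omega`` satisfies the
fixed-point equation

    Omega = (1/(K·P)) · Σ_k (W^(k) − M) · Omega⁻¹ · (W^(k) − M)ᵀ

iterated from the identity.  The raw map has an exact scale indeterminacy:
replacing ``Omega`` by ``c·Omega`` multiplies its image by ``1/c``, so the
scale component of the plain iteration two-cycles instead of converging.
:func:`estimate_omega` therefore rescales each iterate to the likelihood-
optimal scale for its shape (``c² = T/(K·P²)`` with ``T`` the total
quadratic-form trace), which removes the two-cycle without moving the fixed
points, and — for symmetric samples, the model's own regime — falls back
to geodesic (matrix geometric-mean) damping in the rare step where the
full move would raise the negative log-likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    EmptySampleList,
    InsufficientWindows,
    NonPositiveDefiniteOmega,
    NonPositiveDiagonal,
    ShapeMismatch,
    SingularOmega,
)
from .windowing import (
    ConnectivityMatrix,
    TimeSeriesMatrix,
    WindowConfig,
    count_windows,
    window_network_series,
)

__all__ = [
    "EstimatorConfig",
    "OmegaDiagnostics",
    "MVNDEstimate",
    "estimate_mean",
    "omega_update",
    "estimate_omega",
    "neg_log_likelihood",
    "normalize_to_correlation",
    "fit_mvnd",
    "sigma_free_parameters",
    "omega_free_parameters",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class EstimatorConfig:
    """Convergence controls for the Omega fixed-point iteration.

    tol
        Frobenius-norm threshold on the change of Omega between iterates.
    max_iter
        Iteration cap; hitting it returns ``converged=False`` rather than
        raising.
    ridge
        Diagonal loading added to Omega before each inversion.  Default 0:
        with K windows the update is almost always full rank, but very
        short or very few windows may need a small positive value.
    """

    tol: float = 1e-6
    max_iter: int = 100
    ridge: float = 0.0

    def __post_init__(self) -> None:
        if not self.tol > 0:
            raise ValueError(f"tol must be positive, got {self.tol}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be >= 1, got {self.max_iter}")
        if self.ridge < 0:
            raise ValueError(f"ridge must be >= 0, got {self.ridge}")


@dataclass
class OmegaDiagnostics:
    """Convergence record of one Omega estimation."""

    n_iterations: int
    converged: bool
    final_delta: float
    nll_trace: list[float] = field(default_factory=list)


@dataclass
class MVNDEstimate:
    """Fitted matrix-variate normal FC model for one subject."""

    M: ConnectivityMatrix
    Omega_raw: np.ndarray
    Omega: ConnectivityMatrix
    n_iterations: int
    converged: bool
    final_delta: float
    nll_trace: list[float] = field(default_factory=list)


def _stack_samples(samples) -> np.ndarray:
    """Stack sample networks into a (K, P, P) float array."""
    arrays = [
        np.asarray(s.values if isinstance(s, ConnectivityMatrix) else s, dtype=float)
        for s in samples
    ]
    if len(arrays) == 0:
        raise EmptySampleList("at least one sample network is required")
    shape = arrays[0].shape
    if len(shape) != 2 or shape[0] != shape[1]:
        raise ShapeMismatch(f"samples must be square matrices, got shape {shape}")
    for i, a in enumerate(arrays):
        if a.shape != shape:
            raise ShapeMismatch(f"sample {i} has shape {a.shape}, expected {shape}")
    return np.stack(arrays)


def _as_matrix(m) -> np.ndarray:
    return np.asarray(m.values if isinstance(m, ConnectivityMatrix) else m, dtype=float)


def estimate_mean(samples) -> np.ndarray:
    """MLE of the mean network: the entrywise average ``(1/K) Σ_k W^(k)``."""
    return _stack_samples(samples).mean(axis=0)


def _cholesky_or_raise(a: np.ndarray, what: str) -> np.ndarray:
    """Cholesky factor of ``a``, raising :class:`SingularOmega` when it is
    indefinite or numerically singular."""
    try:
        chol = np.linalg.cholesky(a)
    except np.linalg.LinAlgError:
        raise SingularOmega(f"{what} is not positive definite") from None
    d = np.diag(chol)
    # (min d / max d)^2 lower-bounds 1/cond_2; guards near-singular factors.
    rcond = (d.min() / d.max()) ** 2
    if not rcond > 1e-13:
        raise SingularOmega(f"{what} is numerically singular", cond=float(1.0 / rcond))
    return chol


def omega_update(samples, m, omega, ridge: float = 0.0) -> np.ndarray:
    """One raw fixed-point step: ``(1/(K·P)) Σ_k S_k Omega⁻¹ S_kᵀ``
    with residuals ``S_k = W^(k) − M``.

    ``ridge`` adds diagonal loading to Omega before inversion.  Raises
    :class:`SingularOmega` when the (loaded) Omega cannot be inverted.
    """
    w = _stack_samples(samples)
    m = _as_matrix(m)
    omega = _as_matrix(omega)
    k, p, _ = w.shape
    if m.shape != (p, p) or omega.shape != (p, p):
        raise ShapeMismatch(
            f"M {m.shape} / Omega {omega.shape} incompatible with samples {p}×{p}"
        )
    loaded = omega + ridge * np.eye(p) if ridge else omega
    _cholesky_or_raise(0.5 * (loaded + loaded.T), "Omega")
    s = w - m
    # T_k = Omega⁻¹ S_kᵀ, batched over k; update = mean_k(S_k T_k) / P.
    t = np.linalg.solve(loaded, s.transpose(0, 2, 1))
    return np.einsum("kij,kjl->il", s, t) / (k * p)


def _quad_trace_total(s: np.ndarray, omega: np.ndarray) -> float:
    """``Σ_k tr(Omega⁻¹ S_k Omega⁻¹ S_kᵀ)`` for stacked residuals ``s``."""
    b = np.linalg.solve(omega, s)
    c = np.linalg.solve(omega, s.transpose(0, 2, 1))
    return float(np.sum(b * c.transpose(0, 2, 1)))


def neg_log_likelihood(samples, m, omega) -> float:
    """Negative log-likelihood of the samples under ``N(M, Omega ⊗ Omega)``.

    Per sample: ``(P²/2)·ln 2π + P·ln det(Omega) + ½·tr(Omega⁻¹ S Omega⁻¹ Sᵀ)``.
    Raises :class:`NonPositiveDefiniteOmega` when Omega is not PD.
    """
    w = _stack_samples(samples)
    m = _as_matrix(m)
    omega = _as_matrix(omega)
    k, p, _ = w.shape
    try:
        chol = np.linalg.cholesky(omega)
    except np.linalg.LinAlgError:
        raise NonPositiveDefiniteOmega(
            "Omega must be positive definite to evaluate the likelihood"
        ) from None
    logdet = 2.0 * float(np.log(np.diag(chol)).sum())
    quad = _quad_trace_total(w - m, omega)
    return k * (0.5 * p * p * _LOG_2PI + p * logdet) + 0.5 * quad


def _rescale_to_optimal(s: np.ndarray, a: np.ndarray, what: str) -> np.ndarray:
    """Scale ``a`` to the likelihood-optimal magnitude for its shape.

    For fixed shape A the NLL is minimized at ``c·A`` with
    ``c² = T/(K·P²)``, ``T = Σ_k tr(A⁻¹ S_k A⁻¹ S_kᵀ)``.  At any fixed
    point of the raw update c = 1, so rescaling moves no fixed point; it
    only kills the scale two-cycle of the plain iteration.
    """
    k, p, _ = s.shape
    _cholesky_or_raise(a, what)
    t = _quad_trace_total(s, a)
    c2 = t / (k * p * p)
    if not (np.isfinite(c2) and c2 > 0):
        raise SingularOmega(f"{what} update collapsed (zero residual scale)")
    return math.sqrt(c2) * a


def _spd_geometric_mean(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Matrix geometric mean A # B = A^{1/2}(A^{-1/2} B A^{-1/2})^{1/2} A^{1/2}."""
    wa, va = np.linalg.eigh(a)
    wa = np.maximum(wa, np.finfo(float).tiny)
    a_half = (va * np.sqrt(wa)) @ va.T
    a_ihalf = (va / np.sqrt(wa)) @ va.T
    mid = a_ihalf @ b @ a_ihalf
    wm, vm = np.linalg.eigh(0.5 * (mid + mid.T))
    wm = np.maximum(wm, 0.0)
    mid_half = (vm * np.sqrt(wm)) @ vm.T
    g = a_half @ mid_half @ a_half
    return 0.5 * (g + g.T)


def estimate_omega(
    samples, m, config: EstimatorConfig | None = None
) -> tuple[np.ndarray, OmegaDiagnostics]:
    """Fixed-point iteration for the edge-covariance factor Omega.

    Starts from the identity and repeats the scale-corrected update until
    the Frobenius norm of the raw update residual ``‖g(Omega) − Omega‖_F``
    drops below ``config.tol`` (so the returned Omega satisfies the
    fixed-point equation below tol) or ``config.max_iter`` is reached (the
    latter returns ``converged=False``; it is not an error).  ``nll_trace``
    records the negative log-likelihood at the start and after every
    accepted step and is non-increasing.
    """
    cfg = config or EstimatorConfig()
    w = _stack_samples(samples)
    m = _as_matrix(m)
    k, p, _ = w.shape
    if m.shape != (p, p):
        raise ShapeMismatch(f"M has shape {m.shape}, samples are {p}×{p}")
    s = w - m

    omega = np.eye(p)
    nll_prev = neg_log_likelihood(w, m, omega)
    trace = [nll_prev]
    converged = False
    delta = float("inf")
    n_iter = 0
    # The likelihood of the shared-factor model decreases along the
    # scale-corrected iteration when the samples are symmetric (the model's
    # own regime, where the fixed point is a stationary point of the
    # symmetric-factor likelihood); only there is monotonicity enforced.
    # For nonsymmetric samples the Omega defined by the update equation is
    # not a likelihood stationary point, and damping toward monotonicity
    # would stall the iteration short of the fixed point.
    symmetric_samples = bool(np.abs(w - w.transpose(0, 2, 1)).max() < 1e-10)
    for n_iter in range(1, cfg.max_iter + 1):
        a = omega_update(w, m, omega, ridge=cfg.ridge)
        a = 0.5 * (a + a.T)
        # Convergence is judged on the raw update residual, so a converged
        # Omega satisfies the fixed-point equation below tol by construction.
        delta = float(np.linalg.norm(a - omega))
        if delta < cfg.tol:
            converged = True
            break
        cand = _rescale_to_optimal(s, a, "Omega")
        nll_new = neg_log_likelihood(w, m, cand)
        # Geodesic backtracking: halve the step on the SPD manifold until
        # the likelihood no longer degrades (rarely triggers; the plain
        # scale-corrected step is near-monotone already).
        backtracks = 0
        while symmetric_samples and nll_new > nll_prev + 1e-9 and backtracks < 40:
            cand = _rescale_to_optimal(s, _spd_geometric_mean(omega, cand), "Omega")
            nll_new = neg_log_likelihood(w, m, cand)
            backtracks += 1
        omega = cand
        nll_prev = min(nll_prev, nll_new)
        trace.append(nll_new)

    return omega, OmegaDiagnostics(
        n_iterations=n_iter, converged=converged, final_delta=delta, nll_trace=trace
    )


def normalize_to_correlation(
    omega_raw, roi_names: tuple[str, ...] | None = None
) -> ConnectivityMatrix:
    """Symmetric correlation scaling ``D^{-1/2} Omega D^{-1/2}``.

    ``D = diag(Omega)``; the result has a unit diagonal and, for a PSD
    input, entries in [-1, 1].  The high-order FC network is this
    normalized Omega.  Raises :class:`NonPositiveDiagonal` when a
    diagonal entry is not strictly positive.
    """
    omega_raw = _as_matrix(omega_raw)
    d = np.diag(omega_raw)
    bad = np.flatnonzero(~(d > 0))
    if bad.size:
        raise NonPositiveDiagonal(int(bad[0]), float(d[bad[0]]))
    inv_sqrt = 1.0 / np.sqrt(d)
    r = omega_raw * np.outer(inv_sqrt, inv_sqrt)
    r = 0.5 * (r + r.T)
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(r, kind="high_order_Omega", roi_names=roi_names)


def fit_mvnd(
    x: TimeSeriesMatrix,
    window: WindowConfig,
    config: EstimatorConfig | None = None,
    on_degenerate: str = "error",
) -> MVNDEstimate:
    """Full single-subject fit: windowed networks → M → Omega.

    Pipeline: build the K per-window Pearson networks, average them for
    the low-order network M, run the fixed-point iteration for the raw
    covariance factor, and normalize it to the high-order network Omega.
    Requires K >= 2 windows (:class:`InsufficientWindows` otherwise).
    """
    k = count_windows(x.n_volumes, window)
    if k < 2:
        raise InsufficientWindows(
            f"got K={k} window(s) (V={x.n_volumes}, N={window.width}, "
            f"s={window.step}); need at least 2 samples for the covariance MLE"
        )
    nets = window_network_series(x, window, on_degenerate=on_degenerate)
    m_hat = estimate_mean(nets)
    m_hat = 0.5 * (m_hat + m_hat.T)
    np.clip(m_hat, -1.0, 1.0, out=m_hat)
    np.fill_diagonal(m_hat, 1.0)
    m_net = ConnectivityMatrix(m_hat, kind="low_order_M", roi_names=x.roi_names)
    omega_raw, diag = estimate_omega(nets, m_hat, config)
    omega_net = normalize_to_correlation(omega_raw, roi_names=x.roi_names)
    return MVNDEstimate(
        M=m_net,
        Omega_raw=omega_raw,
        Omega=omega_net,
        n_iterations=diag.n_iterations,
        converged=diag.converged,
        final_delta=diag.final_delta,
        nll_trace=diag.nll_trace,
    )


def sigma_free_parameters(p: int) -> int:
    """Free off-diagonal parameters of the unconstrained P²×P² edge
    covariance: ``P²·(P²−1)/2``  (90,525,240 for P=116)."""
    return p * p * (p * p - 1) // 2


def omega_free_parameters(p: int) -> int:
    """Free off-diagonal parameters of the Kronecker factor: ``P·(P−1)/2``."""
    return p * (p - 1) // 2
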