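"""Synthetic matrix-normal ensembles and two-group BOLD-like cohorts.

Two generators make every pipeline stage testable without imaging data:

* :func:`sample_matrix_normal` draws P×P networks from the estimator's
  exact generative model ``W = M + Omega^{1/2} G Omega^{1/2}`` (G i.i.d.
  standard normal), realizing edge covariance ``Omega ⊗ Omega``.  Draws
  are deliberately *not* symmetrized: symmetrization would change the
  covariance away from the Kronecker form and break exact-recovery tests.
  Symmetric, data-like samples come instead from the time-series pathway
  below, whose windowed correlation networks are symmetric by
  construction.

* :func:`simulate_cohort` builds a two-group cohort of V×P time series.
  Group correlation targets share a smooth base structure; the patient
  group's mean network is shifted on a small set of edges (``mean_effect``)
  and/or its between-subject edge variability is inflated
  (``omega_effect``).  Each subject's series is drawn from a zero-mean
  multivariate normal with the group's correlation target plus independent
  observation noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .evaluation import CohortDataset, Subject
from .exceptions import InvalidCorrelationTarget, NonPositiveDefiniteOmega
from .windowing import TimeSeriesMatrix

__all__ = [
    "SimulationSpec",
    "sample_matrix_normal",
    "base_correlation",
    "project_to_correlation",
    "simulate_cohort",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Ground-truth design of a two-group synthetic cohort.

    Defaults describe a desk-scale cohort whose mean-network group
    difference is strong enough to be clearly separable: 10 ROIs, 120
    volumes, 10 subjects per group, a +0.4 shift on 10% of edges for the
    patient group, and observation noise of 0.5 SD (which attenuates the
    observed correlations by a factor 1/(1+0.25) = 0.8).
    """

    n_rois: int = 10
    n_volumes: int = 120
    n_per_group: int = 10
    mean_effect: float = 0.4
    omega_effect: float = 0.0
    noise_sd: float = 0.5
    edge_fraction: float = 0.1
    base_rho: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rois < 2 or self.n_volumes < 2 or self.n_per_group < 1:
            raise ValueError("dimensions must be positive (P>=2, V>=2, n>=1)")
        if self.mean_effect < 0 or self.omega_effect < 0 or self.noise_sd < 0:
            raise ValueError("effects and noise_sd must be non-negative")
        if not 0.0 < self.edge_fraction <= 1.0:
            raise ValueError(f"edge_fraction must be in (0, 1], got {self.edge_fraction}")
        if not 0.0 <= self.base_rho < 1.0:
            raise ValueError(f"base_rho must be in [0, 1), got {self.base_rho}")


def sample_matrix_normal(m, omega, k: int, seed: int) -> list[np.ndarray]:
    """K i.i.d. draws from the matrix-variate normal ``N(M, Omega ⊗ Omega)``.

    Each draw is ``M + R G R`` with ``R`` the symmetric PSD square root of
    Omega and ``G`` a P×P matrix of independent standard normals.  Raises
    :class:`NonPositiveDefiniteOmega` when Omega is not symmetric positive
    definite.
    """
    m = np.asarray(m, dtype=float)
    omega = np.asarray(omega, dtype=float)
    if k < 0:
        raise ValueError(f"number of draws must be >= 0, got {k}")
    p = m.shape[0]
    if m.shape != (p, p) or omega.shape != (p, p):
        raise ValueError(f"M {m.shape} and Omega {omega.shape} must be square and equal")
    if np.abs(omega - omega.T).max() > 1e-10:
        raise NonPositiveDefiniteOmega("Omega must be symmetric")
    w, v = np.linalg.eigh(omega)
    if w.min() <= 1e-12 * max(w.max(), 1.0):
        raise NonPositiveDefiniteOmega(
            f"Omega must be positive definite (min eigenvalue {w.min():.3g})"
        )
    root = (v * np.sqrt(w)) @ v.T
    rng = np.random.default_rng(seed)
    g = rng.standard_normal((k, p, p))
    return list(m + root @ g @ root)


def base_correlation(p: int, rho: float = 0.4) -> np.ndarray:
    """Smooth exponential-decay correlation target ``C[i,j] = rho^|i−j|``.

    Always a valid (positive definite for |rho|<1) correlation matrix;
    stands in for the banded community structure of real FC networks.
    """
    idx = np.arange(p)
    return rho ** np.abs(np.subtract.outer(idx, idx)).astype(float)


def project_to_correlation(a: np.ndarray, eig_floor: float = 1e-6) -> np.ndarray:
    """Nearest-in-spirit valid correlation matrix: eigenvalue clip at a
    small positive floor, then rescale to a unit diagonal."""
    a = 0.5 * (a + a.T)
    w, v = np.linalg.eigh(a)
    s = (v * np.maximum(w, eig_floor)) @ v.T
    d = np.diag(s)
    if not (d > 0).all():
        raise InvalidCorrelationTarget("projection produced a non-positive diagonal")
    inv = 1.0 / np.sqrt(d)
    c = s * np.outer(inv, inv)
    c = 0.5 * (c + c.T)
    np.fill_diagonal(c, 1.0)
    return c


def _group_targets(spec: SimulationSpec, rng: np.random.Generator):
    """Control/patient correlation targets and the perturbed edge set."""
    c1 = base_correlation(spec.n_rois, spec.base_rho)
    iu = np.triu_indices(spec.n_rois, k=1)
    n_edges = iu[0].size
    n_hit = max(1, math.ceil(spec.edge_fraction * n_edges))
    hit = rng.choice(n_edges, size=n_hit, replace=False)
    delta = np.zeros_like(c1)
    rows, cols = iu[0][hit], iu[1][hit]
    delta[rows, cols] = spec.mean_effect
    delta += delta.T
    c2 = project_to_correlation(c1 + delta)
    return c1, c2, (rows, cols)


def simulate_cohort(spec: SimulationSpec) -> CohortDataset:
    """Draw a labeled two-group cohort of BOLD-like ROI time series.

    Controls (label 0) share the base correlation target; patients
    (label 1) share the edge-shifted target, and when ``omega_effect > 0``
    each patient's own target additionally fluctuates on the perturbed
    edges with that SD (creating a between-subject edge-covariance group
    difference).  Every subject stream is derived from the root seed, so
    per-subject data is independent of generation order.
    """
    root = np.random.SeedSequence(spec.seed)
    design_ss, *subject_ss = root.spawn(1 + 2 * spec.n_per_group)
    c1, c2, hit_edges = _group_targets(spec, np.random.default_rng(design_ss))

    subjects: list[Subject] = []
    for s_idx, ss in enumerate(subject_ss):
        group = s_idx // spec.n_per_group  # 0 = controls, 1 = patients
        rng = np.random.default_rng(ss)
        target = c1 if group == 0 else c2
        if group == 1 and spec.omega_effect > 0:
            jitter = np.zeros_like(target)
            rows, cols = hit_edges
            jitter[rows, cols] = rng.normal(0.0, spec.omega_effect, size=rows.size)
            jitter += jitter.T
            target = project_to_correlation(target + jitter)
        chol = np.linalg.cholesky(target)
        signal = rng.standard_normal((spec.n_volumes, spec.n_rois)) @ chol.T
        noise = spec.noise_sd * rng.standard_normal((spec.n_volumes, spec.n_rois))
        label = group
        name = f"{'pt' if label else 'nc'}_{(s_idx % spec.n_per_group) + 1:03d}"
        subjects.append(Subject(id=name, X=TimeSeriesMatrix(signal + noise), label=label))
    return CohortDataset(subjects)
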