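# Methods notes

## Model and estimation procedure

A subject's ROI time-series matrix X (V volumes × P ROIs) is standardized
per column (centered, unit Euclidean norm) so that the Pearson network is
the Gram matrix XᵀX. Sliding windows of width N and step s produce
K = ⌊(V − N)/s⌋ + 1 windowed networks W⁽ᵏ⁾, each standardized *within its
window* — every sample is itself a valid correlation matrix. Trailing
volumes that do not fill a window are discarded (this is what the floor
guarantees); windows are 0-based internally, window k covering rows
k·s … k·s + N − 1.

The W⁽ᵏ⁾ are modeled as draws from a matrix-variate normal N(M, Ω ⊗ Ω)
with a single shared covariance factor, appropriate for symmetric
networks, whose negative log-likelihood per sample is

    (P²/2)·ln 2π + P·ln det Ω + ½·tr(Ω⁻¹ S Ω⁻¹ Sᵀ),   S = W − M.

The MLE of M is the sample mean. The MLE of Ω satisfies the fixed-point
equation Ω = g(Ω) := (1/KP) Σₖ S_k Ω⁻¹ S_kᵀ, iterated from Ω⁰ = I.

### Why the plain iteration cannot converge, and what we do about it

The update map is scale-antisymmetric: g(cΩ) = c⁻¹g(Ω). Its differential
at any fixed point therefore has an exact eigenvalue −1 in the scale
direction, so the plain iteration two-cycles in scale instead of
converging (for the two-sample case W = ±I with M = 0 the iterates from I
oscillate between I and ½·I forever, although the fixed point (1/√2)·I
exists and is unique up to sign). Each iterate is therefore rescaled to
the likelihood-optimal magnitude for its shape: for fixed shape A, the
NLL is minimized at c·A with c² = T/(K·P²), T = Σₖ tr(A⁻¹S_kA⁻¹S_kᵀ).
This rescaling moves no fixed point — at a fixed point of g the optimal
c is exactly 1, and conversely any fixed point of the rescaled map
satisfies c = 1 and hence is a fixed point of g — and it converges on the
analytic example in one step. Non-scale directions of the raw map are
contractive in practice; the package does not rely on a proof of this but
verifies the fixed-point property on every converged fit.

Numerical safeguards:

* each iterate is symmetrized ((A + Aᵀ)/2) to absorb floating-point
  asymmetry;
* convergence is declared on the *raw update residual*
  ‖g(Ω) − Ω‖_F < tol, so a converged Ω satisfies the fixed-point
  equation below tol by construction; `final_delta` reports this residual;
* when the samples are symmetric (the model's own regime, and always the
  case for windowed correlation networks) a geodesic backtracking step —
  replacing an overshooting candidate by its matrix geometric mean with
  the current iterate, then rescaling — enforces a non-increasing NLL
  trace. For *nonsymmetric* samples the Ω defined by the update equation
  is not a stationary point of the shared-factor likelihood, so enforcing
  monotonicity there would stall the iteration short of the fixed point;
  backtracking is disabled and the trace may rise by a relatively tiny
  amount (observed ≲ 1e−5 relative) in mid-iteration;
* correlations are clamped to [−1, 1] and diagonals pinned to exactly 1
  after rounding;
* a singular or indefinite Ω update raises `SingularOmega` with a
  condition estimate rather than producing NaNs (this is also how the
  degenerate all-samples-equal-M case surfaces: the first update is the
  zero matrix).

Estimation of Ω represents covariance scale; the reported high-order
network is the symmetric correlation normalization D^(−1/2)·Ω·D^(−1/2),
D = diag(Ω). `Omega_raw` is kept alongside because the likelihood and the
fixed-point diagnostics live on covariance scale.

## Tunable parameters

| parameter | default | units | why |
| --- | --- | --- | --- |
| window width N | 50 | volumes | short enough to expose dynamics, long enough for a stable P×P correlation; the package's CLI default matches the study-scale choice |
| window step s | 8 | volumes | 11 windows from a 137-volume series |
| tol | 1e−6 | Frobenius norm of the raw update residual | residual scale of a unit-diagonal P×P factor; tighter tolerances should come with a larger `max_iter` (the local contraction ratio is often ≈ 0.8) |
| max_iter | 100 | iterations | ample for tol 1e−6; hitting it returns `converged=False`, never an error |
| ridge | 0 | diagonal loading | K·P residual terms almost always yield a full-rank update; very short or very few windows may need a small positive value |
| threshold grid | 1%, 10%, …, 100% | kept-edge fraction | the 11 standard sparsity levels; 10% means 90% of the weakest edges are removed |
| alpha | 0.05 | t-test level | raw (uncorrected) two-sided pooled-variance two-sample t-test |
| SVM C | 1 | soft-margin constant | the protocol's fixed default; not tuned |

## Evaluation protocol choices

* **Thresholding** ranks edges by |weight|, so strong negative
  correlations survive — standard practice for signed FC networks. Edge
  count is ⌈f·E⌉; ties keep the edge earlier in row-major order, making
  the operation deterministic. Thresholding is applied per subject per
  network type, after fusion (FuMO is a network in its own right and is
  thresholded as one).
* **Feature selection** runs inside every inner training split by default
  (`selection="per-fold"`), so the inner validation subject cannot leak
  into selection; `"outer-train"` reproduces the cheaper variant that
  selects once per outer training set. If no feature reaches p < alpha
  the single smallest-p feature is kept, so degenerate folds cannot crash
  the outer loop.
* **Inner-CV tie-break** chooses the smallest (sparsest) keep-fraction.
* **Outer-fold purity**: the held-out subject's data enters nothing but
  its own prediction — verified by the test suite by perturbing held-out
  subjects and checking the fold's selected threshold, feature mask and
  classifier are bit-identical.

### LOOCV under label permutation is below chance, not at chance

With a balanced cohort, leaving one subject out makes its class the
minority of the training set (9 vs 10 of n−1 = 19), and features selected
because they spuriously separate the permuted training labels place the
held-out subject systematically on the wrong side. The combination drives
nested-LOOCV accuracy under label permutation far *below* 0.5 — typically
0.0–0.1 on this package's synthetic cohorts, occasionally higher when the
permutation happens to retain alignment with the true groups. This is a
well-documented property of leave-one-out protocols with in-fold feature
selection, not an implementation artifact; permutation-based null
calibration of this pipeline should use the full permutation distribution
rather than assuming accuracy ≈ 0.5 under the null.

## Synthetic data

`sample_matrix_normal` draws W = M + Ω^{1/2}·G·Ω^{1/2} with G i.i.d.
standard normal, realizing edge covariance Ω ⊗ Ω exactly. Draws are *not*
symmetrized: symmetrization would change the covariance away from the
Kronecker form and break exact-recovery tests. Symmetric, data-like
samples come from the time-series pathway instead, whose windowed
correlation networks are symmetric by construction.

`simulate_cohort` emulates a two-group resting-state cohort at desk
scale: P = 10 ROIs, V = 120 volumes, 10 subjects per group. The control
group's correlation target is the smooth exponential-decay matrix
ρ^|i−j| (ρ = 0.4), a stand-in for the banded community structure of real
FC; the patient group's target adds +0.4 to a randomly chosen 10% of
edges and is projected back to a valid correlation matrix (eigenvalue
clip at 1e−6, rescale to unit diagonal). Subject series are zero-mean
Gaussian draws from the group target plus independent observation noise
(SD 0.5, attenuating observed correlations by a factor 0.8); with
`omega_effect > 0` each patient's own target additionally fluctuates on
the perturbed edges, creating a between-subject edge-covariance group
difference. Per-subject random streams are spawned from the root seed, so
any subject's data is independent of generation order.

What the generator deliberately does **not** emulate: hemodynamic
response and autocorrelated BOLD spectra, scanner drift and motion
artifacts, band-pass filtering, inter-site heterogeneity, and
parcellation error. Tests passing on these cohorts demonstrate the
correctness and statistical behavior of the estimator and protocol on
their generative model — not classification performance on real rs-fMRI.

## Problem sizes used by the test suite and acceptance script

Fits and cohorts are kept at desk scale — P between 5 and 10 ROIs,
V between 40 and 240 volumes, cohorts of 10–20 subjects, Monte-Carlo
ensembles up to K = 2000 draws at P = 8, and a full window-count
enumeration up to V = 200 — sizes at which every check runs in seconds
while leaving the estimator's O(K·P³) per-iteration cost clearly
exercised. The estimator itself has no dimension-specific shortcuts: the
same code path handles the 116-ROI scale.

## Known limitations

* The shared-factor model assumes Ω₁ = Ω₂; general (Ω₁ ≠ Ω₂)
  matrix-normal estimation and partial-correlation variants are out of
  scope.
* Windowed correlation samples are not truly i.i.d. (windows overlap);
  the MLE is used as a working estimator, as in the underlying protocol.
* The NLL trace is only guaranteed non-increasing for symmetric samples
  (see above).
* `count_windows`/`extract_windows` discard trailing volumes; no partial
  windows.
* The sign of Ω's off-diagonal entries is identified (scale rigidity
  forces c = ±1 and positive diagonals pick c = +1), but a global sign
  flip of the *samples'* residuals leaves the likelihood unchanged, as in
  any covariance model.
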