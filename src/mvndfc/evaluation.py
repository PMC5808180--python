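"""Classification protocol: t-test selection, linear SVM, nested LOOCV.

Mirrors the standard connectome-classification recipe for small cohorts:
for every held-out subject, an inner leave-one-out loop on the remaining
training subjects picks the proportional-threshold level from a sparsity
grid, features are the surviving edge weights filtered by a two-sample
t-test (p < alpha), and a linear soft-margin SVM with C = 1 predicts the
held-out label.  Performance is summarized by accuracy, sensitivity and
specificity from the pooled confusion counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.svm import SVC

from .exceptions import DegenerateClass, MvndfcError, UndefinedMetric
from .mvnd import EstimatorConfig, fit_mvnd
from .network_ops import fuse_networks, threshold_proportional, vectorize_upper
from .windowing import ConnectivityMatrix, TimeSeriesMatrix, WindowConfig, pearson_network

__all__ = [
    "DEFAULT_GRID",
    "NETWORK_TYPES",
    "Subject",
    "CohortDataset",
    "FoldResult",
    "EvaluationResult",
    "ttest_feature_mask",
    "compute_metrics",
    "subject_network",
    "nested_loocv",
]

logger = logging.getLogger(__name__)

#: The 11 sparsity levels of the threshold grid: 1%, 10%, 20%, ..., 100%.
DEFAULT_GRID = (0.01, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)

#: Network feature types: full-series Pearson baseline, low-order mean M,
#: high-order normalized Omega, and their 0.5·(M+Omega) fusion.
NETWORK_TYPES = ("pc", "lom", "hio", "fumo")


@dataclass
class Subject:
    """One cohort member: id, ROI time series, and binary label (1 = patient)."""

    id: str
    X: TimeSeriesMatrix
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass
class CohortDataset:
    """A labeled cohort sharing a common ROI parcellation."""

    subjects: list[Subject]

    def __post_init__(self) -> None:
        if len(self.subjects) < 2:
            raise ValueError("a cohort needs at least two subjects")
        p = self.subjects[0].X.n_rois
        for s in self.subjects:
            if s.X.n_rois != p:
                raise ValueError(
                    f"subject {s.id!r} has {s.X.n_rois} ROIs, expected {p}"
                )
        labels = {s.label for s in self.subjects}
        if labels != {0, 1}:
            raise ValueError("both classes must be non-empty")

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def n_rois(self) -> int:
        return self.subjects[0].X.n_rois

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.subjects], dtype=int)


@dataclass
class FoldResult:
    """Outcome of one outer LOOCV fold."""

    held_out_id: str
    chosen_threshold: float
    predicted_label: int
    true_label: int
    inner_accuracy: float
    feature_mask: np.ndarray = field(repr=False)
    coef: np.ndarray = field(repr=False)
    intercept: float = 0.0


@dataclass
class EvaluationResult:
    """Pooled nested-LOOCV outcome."""

    per_fold: list[FoldResult]
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float

    @property
    def confusion(self) -> tuple[int, int, int, int]:
        return (self.tp, self.tn, self.fp, self.fn)


def ttest_feature_mask(
    features: np.ndarray, labels: np.ndarray, alpha: float = 0.05
) -> np.ndarray:
    """Two-sided pooled-variance two-sample t-test mask, selected at p < alpha.

    A feature with zero pooled variance is never selected.  When no feature
    passes, the single smallest-p feature is kept instead so downstream
    classifiers always see at least one column (logged at DEBUG).
    Raises :class:`DegenerateClass` when either class has < 2 samples.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    a = features[labels == 0]
    b = features[labels == 1]
    if len(a) < 2 or len(b) < 2:
        raise DegenerateClass(
            f"need >= 2 samples per class, got {len(a)} controls / {len(b)} patients"
        )
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant features trigger a scipy precision warning; their NaN
        # p-values are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(a, b, axis=0, equal_var=True)
    p = np.where(np.isfinite(p), p, np.inf)
    mask = p < alpha
    if not mask.any():
        best = int(np.argmin(p))
        logger.debug("no feature reached p < %g; keeping best feature %d", alpha, best)
        mask[best] = True
    return mask


def compute_metrics(tp: int, tn: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Accuracy, sensitivity and specificity from confusion counts.

    accuracy = (TP+TN)/(TP+FP+TN+FN), sensitivity = TP/(TP+FN),
    specificity = TN/(TN+FP).  Raises :class:`UndefinedMetric` on a zero
    denominator.
    """
    counts = (tp, tn, fp, fn)
    if any(c < 0 for c in counts):
        raise ValueError(f"confusion counts must be non-negative, got {counts}")
    if tp + tn + fp + fn == 0:
        raise UndefinedMetric("empty confusion table")
    if tp + fn == 0:
        raise UndefinedMetric("no positive subjects: sensitivity undefined")
    if tn + fp == 0:
        raise UndefinedMetric("no negative subjects: specificity undefined")
    accuracy = (tp + tn) / (tp + tn + fp + fn)
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)
    return accuracy, sensitivity, specificity


def subject_network(
    x: TimeSeriesMatrix,
    network_type: str,
    window: WindowConfig | None = None,
    config: EstimatorConfig | None = None,
    on_degenerate: str = "error",
) -> ConnectivityMatrix:
    """Build one subject's network of the requested type.

    ``pc`` is the full-series Pearson baseline and touches no windowing or
    MVND code; ``lom``/``hio``/``fumo`` run the matrix-normal fit and
    return M, normalized Omega, or their fusion.
    """
    if network_type not in NETWORK_TYPES:
        raise ValueError(f"network_type must be one of {NETWORK_TYPES}, got {network_type!r}")
    if network_type == "pc":
        return pearson_network(x, on_degenerate=on_degenerate)
    if window is None:
        raise ValueError(f"network_type {network_type!r} requires a window configuration")
    est = fit_mvnd(x, window, config, on_degenerate=on_degenerate)
    if network_type == "lom":
        return est.M
    if network_type == "hio":
        return est.Omega
    return fuse_networks(est.M, est.Omega)


def _fit_fold(features, labels, train_rows, cols, c: float = 1.0) -> SVC:
    clf = SVC(kernel="linear", C=c)
    clf.fit(features[np.ix_(train_rows, cols)], labels[train_rows])
    return clf


def nested_loocv(
    dataset: CohortDataset,
    network_type: str = "lom",
    window: WindowConfig | None = None,
    config: EstimatorConfig | None = None,
    grid=DEFAULT_GRID,
    alpha: float = 0.05,
    selection: str = "per-fold",
    on_degenerate: str = "error",
) -> EvaluationResult:
    """Nested leave-one-out cross-validation over the sparsity grid.

    For each outer held-out subject, every grid fraction is scored by an
    inner LOOCV on the n−1 training subjects (threshold → t-test feature
    selection → linear SVM, C = 1); the best fraction wins, ties going to
    the smallest (sparsest) one.  The model is then refit on all n−1
    subjects at that fraction to predict the held-out subject.  The
    held-out subject never influences selection, thresholding choice, or
    training for its own fold.

    ``selection`` controls where the t-test runs: ``"per-fold"`` recomputes
    it inside every inner training split (no leakage into the inner
    validation subject), ``"outer-train"`` computes it once per fraction on
    the full outer training set.
    """
    if len(dataset) < 4:
        raise ValueError("nested LOOCV needs a cohort of at least 4 subjects")
    grid = sorted(float(g) for g in grid)
    if not grid:
        raise ValueError("threshold grid must be non-empty")
    if selection not in ("per-fold", "outer-train"):
        raise ValueError(f"selection must be 'per-fold' or 'outer-train', got {selection!r}")

    # Per-subject networks are computed once and cached across folds.
    networks = []
    for subj in dataset.subjects:
        try:
            networks.append(
                subject_network(subj.X, network_type, window, config, on_degenerate)
            )
        except MvndfcError as exc:
            raise type(exc)(f"subject {subj.id!r}: {exc}") from exc

    # Thresholding depends only on the subject's own network, so the full
    # feature table per grid fraction is also precomputed.
    feats = {
        f: np.vstack(
            [vectorize_upper(threshold_proportional(net, f)).values for net in networks]
        )
        for f in grid
    }
    y = dataset.labels
    n = len(dataset)

    per_fold: list[FoldResult] = []
    tp = tn = fp = fn = 0
    for i in range(n):
        train = np.array([j for j in range(n) if j != i])
        best_frac, best_acc = grid[0], -1.0
        for frac in grid:
            f_tr = feats[frac][train]
            y_tr = y[train]
            if selection == "outer-train":
                mask = ttest_feature_mask(f_tr, y_tr, alpha)
                cols = np.flatnonzero(mask)
            hits = 0
            for j in range(len(train)):
                inner = np.array([r for r in range(len(train)) if r != j])
                if selection == "per-fold":
                    mask = ttest_feature_mask(f_tr[inner], y_tr[inner], alpha)
                    cols = np.flatnonzero(mask)
                clf = _fit_fold(f_tr, y_tr, inner, cols)
                pred = clf.predict(f_tr[j, cols].reshape(1, -1))[0]
                hits += int(pred == y_tr[j])
            acc = hits / len(train)
            if acc > best_acc:  # ties keep the earlier (smaller) fraction
                best_acc, best_frac = acc, frac
        f_best = feats[best_frac]
        mask = ttest_feature_mask(f_best[train], y[train], alpha)
        cols = np.flatnonzero(mask)
        clf = _fit_fold(f_best, y, train, cols)
        pred = int(clf.predict(f_best[i, cols].reshape(1, -1))[0])
        truth = int(y[i])
        tp += pred == 1 and truth == 1
        tn += pred == 0 and truth == 0
        fp += pred == 1 and truth == 0
        fn += pred == 0 and truth == 1
        per_fold.append(
            FoldResult(
                held_out_id=dataset.subjects[i].id,
                chosen_threshold=best_frac,
                predicted_label=pred,
                true_label=truth,
                inner_accuracy=best_acc,
                feature_mask=mask,
                coef=clf.coef_.ravel().copy(),
                intercept=float(clf.intercept_[0]),
            )
        )

    accuracy, sensitivity, specificity = compute_metrics(tp, tn, fp, fn)
    return EvaluationResult(
        per_fold=per_fold,
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
    )
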