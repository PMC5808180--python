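"""Delimited-text readers/writers and run configuration.

Time-series files are plain CSV/TSV: rows = volumes, columns = ROIs, with
an optional header row of ROI names; the delimiter is auto-detected among
comma and tab.  Output matrices are written at full double precision
(17 significant digits) so a write/read round trip is lossless.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import DEFAULT_GRID, CohortDataset, EvaluationResult, Subject
from .exceptions import ParseError, RaggedRows
from .mvnd import EstimatorConfig, MVNDEstimate
from .windowing import ConnectivityMatrix, TimeSeriesMatrix, WindowConfig

__all__ = [
    "RunConfig",
    "read_timeseries",
    "read_delimited",
    "write_matrix",
    "read_matrix",
    "write_diagnostics",
    "write_evaluation",
    "read_manifest",
    "write_cohort",
]


def _detect_delimiter(first_line: str) -> str:
    return "\t" if "\t" in first_line else ","


def _parse_cell(cell: str, row: int, col: int) -> float:
    text = cell.strip()
    try:
        value = float(text)
    except ValueError:
        raise ParseError(
            f"non-numeric cell {text!r} at row {row}, column {col}", row=row, col=col
        ) from None
    if not np.isfinite(value):
        raise ParseError(
            f"non-finite cell {text!r} at row {row}, column {col}", row=row, col=col
        )
    return value


def read_delimited(path) -> tuple[np.ndarray, tuple[str, ...] | None]:
    """Read a rectangular numeric CSV/TSV, returning (values, header or None).

    The first row is treated as a header of names when any of its cells is
    non-numeric.  Malformed cells raise :class:`ParseError` with 1-based
    file coordinates; inconsistent row lengths raise :class:`RaggedRows`.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        first = fh.readline()
        if not first.strip():
            raise ParseError(f"{path} is empty")
        fh.seek(0)
        rows = [r for r in csv.reader(fh, delimiter=_detect_delimiter(first)) if r]
    width = len(rows[0])
    for i, r in enumerate(rows):
        if len(r) != width:
            raise RaggedRows(
                f"row {i + 1} has {len(r)} cells, expected {width}", row=i + 1
            )

    names: tuple[str, ...] | None = None
    start = 0
    try:
        [float(c) for c in rows[0]]
    except ValueError:
        names = tuple(c.strip() for c in rows[0])
        start = 1
    if start == len(rows):
        raise ParseError(f"{path} has a header but no data rows")
    values = np.array(
        [
            [_parse_cell(c, i + start + 1, j + 1) for j, c in enumerate(row)]
            for i, row in enumerate(rows[start:])
        ]
    )
    return values, names


def read_timeseries(path) -> TimeSeriesMatrix:
    """Read one subject's V×P ROI time series from delimited text."""
    values, names = read_delimited(path)
    try:
        return TimeSeriesMatrix(values, roi_names=names)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_matrix(path, matrix, roi_names=None) -> None:
    """Write a matrix as CSV at full double precision (17 sig. digits)."""
    values = matrix.values if isinstance(matrix, ConnectivityMatrix) else np.asarray(matrix)
    if roi_names is None and isinstance(matrix, ConnectivityMatrix):
        roi_names = matrix.roi_names
    with open(path, "w", newline="") as fh:
        if roi_names is not None:
            fh.write(",".join(roi_names) + "\n")
        for row in values:
            fh.write(",".join(f"{v:.17g}" for v in row) + "\n")


def read_matrix(path) -> tuple[np.ndarray, tuple[str, ...] | None]:
    """Read back a matrix written by :func:`write_matrix`."""
    return read_delimited(path)


def write_diagnostics(path, estimate: MVNDEstimate) -> None:
    """Write convergence diagnostics of one fit as a JSON sidecar."""
    with open(path, "w") as fh:
        json.dump(
            {
                "n_iterations": estimate.n_iterations,
                "converged": estimate.converged,
                "final_delta": estimate.final_delta,
                "nll_trace": list(estimate.nll_trace),
            },
            fh,
            indent=2,
        )
        fh.write("\n")


def write_evaluation(path, result: EvaluationResult) -> None:
    """Write nested-LOOCV results (per-fold records + summary) as JSON."""
    payload = {
        "confusion": {"tp": result.tp, "tn": result.tn, "fp": result.fp, "fn": result.fn},
        "accuracy": result.accuracy,
        "sensitivity": result.sensitivity,
        "specificity": result.specificity,
        "per_fold": [
            {
                "held_out_id": f.held_out_id,
                "chosen_threshold": f.chosen_threshold,
                "predicted_label": f.predicted_label,
                "true_label": f.true_label,
                "inner_accuracy": f.inner_accuracy,
                "n_features_selected": int(f.feature_mask.sum()),
            }
            for f in result.per_fold
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_manifest(path) -> CohortDataset:
    """Load a cohort from a manifest CSV with columns id, path, label.

    Relative subject paths are resolved against the manifest's directory.
    """
    path = Path(path)
    table = pd.read_csv(path)
    missing = {"id", "path", "label"} - set(table.columns)
    if missing:
        raise ParseError(f"manifest {path} lacks column(s) {sorted(missing)}")
    subjects = []
    for rec in table.itertuples(index=False):
        label = int(rec.label)
        sub_path = Path(rec.path)
        if not sub_path.is_absolute():
            sub_path = path.parent / sub_path
        subjects.append(Subject(id=str(rec.id), X=read_timeseries(sub_path), label=label))
    return CohortDataset(subjects)


def write_cohort(out_dir, dataset: CohortDataset) -> Path:
    """Write per-subject CSV files plus a manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for subj in dataset.subjects:
        fname = f"{subj.id}.csv"
        write_matrix(out_dir / fname, subj.X.values, roi_names=subj.X.roi_names)
        records.append({"id": subj.id, "path": fname, "label": subj.label})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(records).to_csv(manifest, index=False)
    return manifest


@dataclass
class RunConfig:
    """JSON-round-trippable configuration of a full pipeline run."""

    window: WindowConfig = field(default_factory=lambda: WindowConfig(width=50, step=8))
    estimator: EstimatorConfig = field(default_factory=EstimatorConfig)
    grid: tuple[float, ...] = DEFAULT_GRID
    alpha: float = 0.05
    network_type: str = "lom"
    seed: int = 0
    on_degenerate: str = "error"

    def to_dict(self) -> dict:
        return {
            "window": {"width": self.window.width, "step": self.window.step},
            "estimator": asdict(self.estimator),
            "grid": list(self.grid),
            "alpha": self.alpha,
            "network_type": self.network_type,
            "seed": self.seed,
            "on_degenerate": self.on_degenerate,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {
            "window",
            "estimator",
            "grid",
            "alpha",
            "network_type",
            "seed",
            "on_degenerate",
        }
        unknown = set(data) - known
        if unknown:
            raise ParseError(f"unknown configuration key(s): {sorted(unknown)}")
        kwargs: dict = {}
        if "window" in data:
            kwargs["window"] = WindowConfig(**data["window"])
        if "estimator" in data:
            kwargs["estimator"] = EstimatorConfig(**data["estimator"])
        if "grid" in data:
            kwargs["grid"] = tuple(float(g) for g in data["grid"])
        for key in ("alpha", "network_type", "seed", "on_degenerate"):
            if key in data:
                kwargs[key] = data[key]
        return cls(**kwargs)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls.from_dict(json.loads(text))
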