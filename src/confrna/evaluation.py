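"""Confusion counts, classification metrics, and the F1 correlation matrix.

Metrics follow the one-vs-rest convention per class:

    accuracy    = (TP + TN) / (TP + FP + FN + TN)
    sensitivity = TP / (TP + FN)
    precision   = TP / (TP + FP)
    F1          = 2 TP / (2 TP + FP + FN)   [harmonic mean of the above two]

Macro averaging (the default) takes the unweighted mean over classes;
micro averaging pools the counts first.  In single-label multiclass
classification micro precision = micro sensitivity = overall accuracy,
which is why benchmark tables sometimes show accuracy equal to
precision.  A plain correct/total "overall accuracy" is always reported
alongside.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "metrics",
    "per_family_metrics",
    "f1_correlation_matrix",
    "write_metrics_tsv",
    "write_metrics_json",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest TP/TN/FP/FN per class, plus the raw confusion matrix."""

    classes: tuple[str, ...]
    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    matrix: np.ndarray  # rows = true class, columns = predicted class

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    def support(self) -> np.ndarray:
        return self.tp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    sensitivity: float
    precision: float
    f1: float
    averaging: str
    overall_accuracy: float
    zero_division: bool = False

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "precision": self.precision,
            "f1": self.f1,
            "averaging": self.averaging,
            "overall_accuracy": self.overall_accuracy,
        }


def confusion(y_true, y_pred, families) -> ConfusionCounts:
    """Count one-vs-rest TP/TN/FP/FN for each family."""
    families = list(families)
    index = {f: i for i, f in enumerate(families)}
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted")
    n = len(families)
    matrix = np.zeros((n, n), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        if t not in index:
            raise ValueError(f"unknown true label {t!r}")
        if p not in index:
            raise ValueError(f"unknown predicted label {p!r}")
        matrix[index[t], index[p]] += 1
    tp = np.diag(matrix).copy()
    fp = matrix.sum(axis=0) - tp
    fn = matrix.sum(axis=1) - tp
    tn = matrix.sum() - tp - fp - fn
    return ConfusionCounts(tuple(families), tp, tn, fp, fn, matrix)


def _safe_divide(num: np.ndarray, den: np.ndarray) -> tuple[np.ndarray, bool]:
    """Elementwise num/den with 0/0 -> 0; flags whether any denominator was 0."""
    den = np.asarray(den, dtype=np.float64)
    num = np.asarray(num, dtype=np.float64)
    hit_zero = bool(np.any(den == 0))
    out = np.divide(num, den, out=np.zeros_like(num, dtype=np.float64), where=den != 0)
    return out, hit_zero


def metrics(counts: ConfusionCounts, averaging: str = "macro") -> MetricsReport:
    """Aggregate the four metrics under macro or micro averaging."""
    if averaging not in ("macro", "micro"):
        raise ValueError(f"averaging must be 'macro' or 'micro', got {averaging!r}")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    overall = float(tp.sum() / counts.total) if counts.total else 0.0
    if averaging == "micro":
        tp, tn, fp, fn = (np.array([v.sum()]) for v in (tp, tn, fp, fn))
    acc, z1 = _safe_divide(tp + tn, tp + fp + fn + tn)
    sens, z2 = _safe_divide(tp, tp + fn)
    prec, z3 = _safe_divide(tp, tp + fp)
    f1, z4 = _safe_divide(2 * tp, 2 * tp + fp + fn)
    flag = z1 or z2 or z3 or z4
    if flag:
        warnings.warn("a metric denominator was zero; affected values reported as 0",
                      RuntimeWarning, stacklevel=2)
    return MetricsReport(
        accuracy=float(acc.mean()),
        sensitivity=float(sens.mean()),
        precision=float(prec.mean()),
        f1=float(f1.mean()),
        averaging=averaging,
        overall_accuracy=overall,
        zero_division=flag,
    )


def per_family_metrics(counts: ConfusionCounts) -> dict[str, MetricsReport]:
    """A one-vs-rest MetricsReport for every family."""
    out: dict[str, MetricsReport] = {}
    for i, family in enumerate(counts.classes):
        tp, tn, fp, fn = (int(v[i]) for v in (counts.tp, counts.tn, counts.fp, counts.fn))
        total = tp + tn + fp + fn
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            acc, _ = _safe_divide(np.array([tp + tn]), np.array([total]))
            sens, _ = _safe_divide(np.array([tp]), np.array([tp + fn]))
            prec, _ = _safe_divide(np.array([tp]), np.array([tp + fp]))
            f1, _ = _safe_divide(np.array([2 * tp]), np.array([2 * tp + fp + fn]))
        out[family] = MetricsReport(
            accuracy=float(acc[0]), sensitivity=float(sens[0]),
            precision=float(prec[0]), f1=float(f1[0]),
            averaging="binary", overall_accuracy=float(acc[0]),
            zero_division=(tp + fn == 0) or (tp + fp == 0),
        )
    return out


def f1_correlation_matrix(per_fold_f1: np.ndarray) -> np.ndarray:
    """Pearson correlation between family columns across CV folds.

    Input: (n_folds, n_families) per-fold F1 scores, n_folds >= 3.
    Output: symmetric (n_families, n_families) matrix with unit diagonal;
    columns with zero variance yield NaN against every other column.
    """
    per_fold_f1 = np.asarray(per_fold_f1, dtype=np.float64)
    if per_fold_f1.ndim != 2:
        raise ValueError("expected a folds x families matrix")
    if per_fold_f1.shape[0] < 3:
        raise ValueError("correlation needs at least 3 folds")
    centered = per_fold_f1 - per_fold_f1.mean(axis=0)
    cov = centered.T @ centered
    std = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = cov / np.outer(std, std)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, np.where(std > 0, 1.0, np.nan))
    return corr


def write_metrics_tsv(reports: dict[str, MetricsReport], path: str | Path) -> None:
    """Flat (metric, class, value) TSV, one row per metric per class."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["metric", "class", "value"])
        for cls, report in reports.items():
            for name in ("accuracy", "sensitivity", "precision", "f1"):
                writer.writerow([name, cls, f"{getattr(report, name):.6f}"])


def write_metrics_json(report: MetricsReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.as_dict(), indent=2) + "\n")
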