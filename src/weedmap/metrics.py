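"""Pixel-level evaluation of predicted weed cover maps against ground truth.

All metrics are derived from a K×K confusion matrix whose rows are
ground-truth classes and columns predicted classes; ground-truth ignore
pixels contribute to no cell.  Overall accuracy is the trace over the total;
mean IU averages per-class intersection-over-union
``c_ii / (row_i + col_i − c_ii)`` over the classes that occur in either the
ground truth or the predictions.  The row-normalized matrix reproduces the
per-class recognition rates conventionally reported for weed maps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .georaster import CLASS_NAMES, CODE_IGNORE, LabelMap


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # K×K int64, rows = GT, cols = predicted
    class_names: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise ValueError(f"expected {k}×{k} counts, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.counts, index=list(self.class_names),
                     columns=list(self.class_names)).to_csv(path)


@dataclass
class EvalReport:
    overall_accuracy: float
    mean_iu: float
    per_class_iu: dict[str, float]
    row_normalized: np.ndarray

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "overall_accuracy": self.overall_accuracy,
            "mean_iu": self.mean_iu,
            "per_class_iu": self.per_class_iu,
            "row_normalized": np.asarray(self.row_normalized).tolist(),
        }, indent=2))


def accumulate_confusion(gt: LabelMap | np.ndarray, pred: LabelMap | np.ndarray,
                         num_classes: int = len(CLASS_NAMES)) -> ConfusionMatrix:
    """Count (gt, pred) pixel pairs, skipping ground-truth ignore pixels."""
    g = gt.codes if isinstance(gt, LabelMap) else np.asarray(gt)
    p = pred.codes if isinstance(pred, LabelMap) else np.asarray(pred)
    if g.shape != p.shape:
        raise ValueError(f"shape mismatch: gt {g.shape} vs pred {p.shape}")
    valid = g != CODE_IGNORE
    g, p = g[valid].astype(np.int64), p[valid].astype(np.int64)
    keep = p != CODE_IGNORE  # predictions on GT-ignore are already gone
    g, p = g[keep], p[keep]
    counts = np.bincount(g * num_classes + p, minlength=num_classes**2)
    return ConfusionMatrix(counts.reshape(num_classes, num_classes))


def overall_accuracy(cm: ConfusionMatrix) -> float:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def mean_iu(cm: ConfusionMatrix) -> float:
    """Mean intersection-over-union over the classes present in GT or prediction."""
    c = cm.counts
    row, col, diag = c.sum(axis=1), c.sum(axis=0), np.diag(c)
    present = (row + col) > 0
    if not present.any():
        raise ValueError("all-zero confusion matrix")
    iu = diag[present] / (row[present] + col[present] - diag[present])
    return float(iu.mean())


def per_class_iu(cm: ConfusionMatrix) -> dict[str, float]:
    c = cm.counts
    row, col, diag = c.sum(axis=1), c.sum(axis=0), np.diag(c)
    out = {}
    for i, name in enumerate(cm.class_names):
        denom = row[i] + col[i] - diag[i]
        out[name] = float(diag[i] / denom) if denom > 0 else float("nan")
    return out


def row_normalize(cm: ConfusionMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Divide each row by its sum; returns (fractions, empty_row_flags)."""
    row = cm.counts.sum(axis=1, keepdims=True)
    empty = row[:, 0] == 0
    out = np.divide(cm.counts, row, where=row > 0, out=np.zeros(cm.counts.shape))
    out[empty] = 0.0
    return out, empty


def evaluate(gt: LabelMap | np.ndarray, pred: LabelMap | np.ndarray) -> EvalReport:
    """One-call evaluation producing the standard report."""
    cm = accumulate_confusion(gt, pred)
    rn, _ = row_normalize(cm)
    return EvalReport(overall_accuracy(cm), mean_iu(cm), per_class_iu(cm), rn)
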