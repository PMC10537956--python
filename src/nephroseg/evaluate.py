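"""Pixel-wise multiclass evaluation: confusion matrix and derived metrics.

Rows of the confusion matrix are ground-truth classes, columns predicted
classes, in schema order. Per-class metrics follow the one-vs-rest
convention:

* precision  = TP / (TP + FP)
* recall     = TP / (TP + FN)
* specificity = TN / (TN + FP)
* F1 = 2 * precision * recall / (precision + recall) = 2TP / (2TP + FP + FN)

A zero denominator yields ``None`` (an undefined marker), which is excluded
from macro summaries rather than propagating as NaN. Ground-truth pixels
carrying the UNANNOTATED sentinel never enter the counts, because ground
truth is sparse region annotation, not a dense labelling.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import UNANNOTATED, ClassSchema, LabelMask
from .net import downsample_mask, upsample_mask


@dataclass(frozen=True)
class ConfusionMatrix:
    counts: np.ndarray  # (K, K) int64, rows = truth, cols = prediction

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (c < 0).any():
            raise ValueError("confusion matrix entries must be non-negative")

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, class_id: int) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) for one class."""
        c = self.counts
        tp = int(c[class_id, class_id])
        fp = int(c[:, class_id].sum()) - tp
        fn = int(c[class_id, :].sum()) - tp
        tn = self.total - tp - fp - fn
        return tp, fp, fn, tn


def confusion_matrix(
    gt: LabelMask,
    pred: LabelMask,
    schema: ClassSchema,
    align: str = "downsample-gt",
) -> ConfusionMatrix:
    """Pixel-wise confusion counts between ground truth and prediction.

    When the grids differ (full-resolution truth vs 8x prediction) the truth
    is block-majority-downsampled to the prediction grid by default
    (``align="downsample-gt"``); ``align="upsample-pred"`` replicates the
    prediction to the truth grid instead. UNANNOTATED truth pixels are
    excluded.
    """
    if gt.downsample_factor != pred.downsample_factor:
        if align == "downsample-gt" and gt.downsample_factor == 1:
            gt = downsample_mask(gt, schema, pred.downsample_factor)
        elif align == "upsample-pred" and pred.downsample_factor > gt.downsample_factor:
            pred = upsample_mask(pred, pred.downsample_factor // gt.downsample_factor)
        else:
            raise ValueError("cannot align mask grids with the requested mode")
    if gt.labels.shape != pred.labels.shape:
        raise ValueError(
            f"grid mismatch: truth {gt.labels.shape} vs prediction {pred.labels.shape}"
        )
    gt.validate_against(schema)
    pred.validate_against(schema)
    k = schema.n_classes
    t = gt.labels.ravel()
    p = pred.labels.ravel()
    valid = t != UNANNOTATED
    t, p = t[valid].astype(np.int64), p[valid].astype(np.int64)
    counts = np.bincount(t * k + p, minlength=k * k).reshape(k, k)
    return ConfusionMatrix(counts)


def row_normalize(cm: ConfusionMatrix) -> np.ndarray:
    """Row percentages: each ground-truth row sums to 100; empty rows are NaN."""
    c = cm.counts.astype(float)
    totals = c.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 100.0 * c / totals
    out[totals.ravel() == 0, :] = np.nan
    return out


@dataclass(frozen=True)
class ClassMetrics:
    """Per-class one-vs-rest metrics; ``None`` marks an undefined value."""

    precision: tuple[float | None, ...]
    recall: tuple[float | None, ...]
    specificity: tuple[float | None, ...]
    f1: tuple[float | None, ...]


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def f1_from_precision_recall(precision: float, recall: float) -> float | None:
    """Harmonic mean of precision and recall; None when both are zero."""
    if precision + recall == 0:
        return None
    return 2.0 * precision * recall / (precision + recall)


def class_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    if cm.n_classes < 2:
        raise ValueError("need at least 2 classes")
    prec, rec, spec, f1 = [], [], [], []
    for cid in range(cm.n_classes):
        tp, fp, fn, tn = cm.one_vs_rest(cid)
        prec.append(_ratio(tp, tp + fp))
        rec.append(_ratio(tp, tp + fn))
        spec.append(_ratio(tn, tn + fp))
        f1.append(None if 2 * tp + fp + fn == 0 else 2 * tp / (2 * tp + fp + fn))
    return ClassMetrics(tuple(prec), tuple(rec), tuple(spec), tuple(f1))


@dataclass(frozen=True)
class MacroSummary:
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float


def macro_summary(metrics: ClassMetrics, cm: ConfusionMatrix) -> MacroSummary:
    """Unweighted and ground-truth-pixel-weighted means over defined classes."""
    support = cm.counts.sum(axis=1).astype(float)

    def agg(values: tuple[float | None, ...]) -> tuple[float, float]:
        defined = [(v, support[i]) for i, v in enumerate(values) if v is not None]
        if not defined:
            raise ValueError("all classes undefined; nothing to summarise")
        vals = np.array([v for v, _ in defined])
        wts = np.array([w for _, w in defined])
        macro = float(vals.mean())
        weighted = float((vals * wts).sum() / wts.sum()) if wts.sum() else macro
        return macro, weighted

    mp, wp = agg(metrics.precision)
    mr, wr = agg(metrics.recall)
    mf, wf = agg(metrics.f1)
    return MacroSummary(mp, mr, mf, wp, wr, wf)


# ---------------------------------------------------------------------------
# tabular / graphical outputs
# ---------------------------------------------------------------------------


def metrics_table(metrics: ClassMetrics, schema: ClassSchema) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "class": [c.name for c in schema.classes],
            "precision": metrics.precision,
            "recall": metrics.recall,
            "specificity": metrics.specificity,
            "f1": metrics.f1,
        }
    )


def confusion_table(
    cm: ConfusionMatrix, schema: ClassSchema, percent: bool = False
) -> pd.DataFrame:
    data = row_normalize(cm) if percent else cm.counts
    names = [c.name for c in schema.classes]
    return pd.DataFrame(data, index=names, columns=names)


def plot_confusion(
    cm: ConfusionMatrix, schema: ClassSchema, path: str | Path
) -> None:
    """Heat-styled row-percentage confusion matrix PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pct = row_normalize(cm)
    names = [c.name for c in schema.classes]
    fig, ax = plt.subplots(figsize=(8, 7))
    im = ax.imshow(np.nan_to_num(pct), cmap="viridis", vmin=0, vmax=100)
    ax.set_xticks(range(len(names)), names, rotation=90, fontsize=7)
    ax.set_yticks(range(len(names)), names, fontsize=7)
    ax.set_xlabel("predicted class (% of ground-truth pixels)")
    ax.set_ylabel("ground-truth class")
    for i in range(len(names)):
        for j in range(len(names)):
            if np.isfinite(pct[i, j]) and pct[i, j] >= 1:
                ax.text(j, i, f"{pct[i, j]:.0f}", ha="center", va="center", fontsize=6)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
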