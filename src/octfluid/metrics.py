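"""Per-class segmentation metrics: precision, recall, F1, Dice, ROC/AUC.

Counts are pooled pixel-wise over a dataset (micro-averaging) by default;
macro (per-image) averaging is available by flag.  Degenerate 0/0 ratios
are reported as 0 (Dice of two empty masks as 1) and flagged.  ROC curves
are built by sweeping the unique scores as thresholds with ties grouped,
and AUC by the trapezoid rule; the same quantity equals the Mann-Whitney
pairwise-comparison statistic, which the tests exploit as an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, ShapeError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


def confusion_counts(pred: np.ndarray, truth: np.ndarray,
                     cls: int) -> ConfusionCounts:
    """One-vs-rest pixel counts for class `cls`."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ShapeError(f"pred {pred.shape} vs truth {truth.shape}")
    p = pred == cls
    t = truth == cls
    tp = int(np.logical_and(p, t).sum())
    fp = int(np.logical_and(p, ~t).sum())
    fn = int(np.logical_and(~p, t).sum())
    tn = int(np.logical_and(~p, ~t).sum())
    return ConfusionCounts(tp, fp, fn, tn)


def precision_recall_f1(c: ConfusionCounts) -> tuple:
    """(precision, recall, f1, degenerate): 0/0 ratios report 0, flagged."""
    degenerate = False
    if c.tp + c.fp == 0:
        precision, degenerate = 0.0, True
    else:
        precision = c.tp / (c.tp + c.fp)
    if c.tp + c.fn == 0:
        recall, degenerate = 0.0, True
    else:
        recall = c.tp / (c.tp + c.fn)
    if precision + recall == 0:
        f1, degenerate = 0.0, True
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return precision, recall, f1, degenerate


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """2|A n B| / (|A| + |B|); two empty masks give 1 by convention."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ShapeError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """(FPR, TPR) points from a descending threshold sweep over the unique
    scores, ties grouped; starts at (0,0) and ends at (1,1)."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(bool)
    if labels.all() or not labels.any():
        raise ConfigError("ROC requires both classes present in labels")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    l = labels[order]
    # indices where the score changes: complete tie groups
    distinct = np.nonzero(np.diff(s))[0]
    idx = np.r_[distinct, s.size - 1]
    tps = np.cumsum(l)[idx]
    fps = np.cumsum(~l)[idx]
    P = labels.sum()
    N = labels.size - P
    tpr = np.r_[0.0, tps / P]
    fpr = np.r_[0.0, fps / N]
    return np.column_stack([fpr, tpr])


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple:
    """ROC curve and trapezoid AUC."""
    curve = roc_curve(scores, labels)
    auc = float(np.trapezoid(curve[:, 1], curve[:, 0]))
    return curve, auc


@dataclass(frozen=True)
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    dice: float
    auc: float
    degenerate: bool = False


@dataclass
class MetricsReport:
    """Per-class and averaged segmentation quality over a dataset."""

    per_class: dict = field(default_factory=dict)  # class id -> ClassMetrics
    n_images: int = 0
    class_names: dict = field(default_factory=lambda: {1: "IRF", 2: "SRF",
                                                       3: "PED"})

    def average(self, metric: str) -> float:
        vals = [getattr(m, metric) for m in self.per_class.values()
                if not (m.degenerate and metric != "auc")]
        return float(np.mean(vals)) if vals else 0.0

    @property
    def mean_dice(self) -> float:
        return self.average("dice")

    def summary(self) -> str:
        """Delimited per-class table with an Average row."""
        header = f"{'Class':<8}{'Pr':>8}{'Re':>8}{'F1':>8}{'Dice':>8}{'AUC':>8}"
        lines = [header, "-" * len(header)]
        for cls in sorted(self.per_class):
            m = self.per_class[cls]
            name = self.class_names.get(cls, str(cls))
            flag = "*" if m.degenerate else ""
            lines.append(f"{name + flag:<8}{m.precision:>8.3f}{m.recall:>8.3f}"
                         f"{m.f1:>8.3f}{m.dice:>8.3f}{m.auc:>8.3f}")
        lines.append(
            f"{'Average':<8}{self.average('precision'):>8.3f}"
            f"{self.average('recall'):>8.3f}{self.average('f1'):>8.3f}"
            f"{self.average('dice'):>8.3f}{self.average('auc'):>8.3f}")
        lines.append(f"n_images = {self.n_images}"
                     + ("   (* degenerate: no pixels of this class)"
                        if any(m.degenerate for m in self.per_class.values())
                        else ""))
        return "\n".join(lines)


def report_from_predictions(preds: list, truths: list, score_maps: list,
                            n_classes: int = 3, macro: bool = False
                            ) -> MetricsReport:
    """Aggregate label masks + per-class score maps into a MetricsReport.

    `macro=True` averages per-image metrics (degenerate images excluded);
    the default pools pixel counts dataset-wide (micro).
    """
    if len(preds) != len(truths):
        raise ShapeError("pred/truth list lengths differ")
    report = MetricsReport(n_images=len(preds))
    for cls in range(1, n_classes + 1):
        scores = np.concatenate(
            [s[cls - 1].ravel() for s in score_maps]) if score_maps else None
        labels = np.concatenate([(t == cls).ravel().astype(int)
                                 for t in truths])
        if scores is not None and 0 < labels.sum() < labels.size:
            _, auc = roc_auc(scores, labels)
        else:
            auc = np.nan
        if macro:
            rows = []
            for p, t in zip(preds, truths):
                c = confusion_counts(p, t, cls)
                pr, re, f1, deg = precision_recall_f1(c)
                if not deg:
                    rows.append((pr, re, f1,
                                 dice_coefficient(p == cls, t == cls)))
            if rows:
                pr, re, f1, dc = map(float, np.mean(rows, axis=0))
                report.per_class[cls] = ClassMetrics(pr, re, f1, dc, auc)
            else:
                report.per_class[cls] = ClassMetrics(0, 0, 0, 1.0, auc,
                                                     degenerate=True)
        else:
            total = ConfusionCounts(0, 0, 0, 0)
            for p, t in zip(preds, truths):
                total = total + confusion_counts(p, t, cls)
            pr, re, f1, deg = precision_recall_f1(total)
            dice = (1.0 if total.tp + total.fp + total.fn == 0
                    else 2 * total.tp / (2 * total.tp + total.fp + total.fn))
            report.per_class[cls] = ClassMetrics(pr, re, f1, dice, auc,
                                                 degenerate=deg)
    return report


def evaluate(model, dataset: list, threshold: float = 0.5,
             macro: bool = False) -> MetricsReport:
    """Run the network over prepared samples and score against their masks.

    `dataset` is a list of training-module Samples (enhanced image, edge
    map, ground-truth mask); images are standardized exactly as during
    training before the forward pass.
    """
    from .network import predict_mask
    from .training import normalize_inputs

    preds, truths, scores = [], [], []
    for s in dataset:
        if s.mask is None:
            raise ConfigError("evaluate requires ground-truth masks")
        probs = model.predict(normalize_inputs(s.image), s.edge)
        preds.append(predict_mask(probs, threshold))
        truths.append(np.asarray(s.mask))
        scores.append(probs)
    return report_from_predictions(preds, truths, scores,
                                   n_classes=model.spec.n_classes,
                                   macro=macro)
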