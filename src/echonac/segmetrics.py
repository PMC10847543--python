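"""Pixel-level segmentation evaluation.

Per-class (normal/cancer) confusion counts, the five standard metrics
(accuracy, IoU, precision, recall, F1), macro averages, the algebraic
F1/IoU identities, and pooled-pixel ROC / precision-recall curves.

Undefined ratios (0/0) are reported as NaN rather than coerced to 0 or 1,
so averages over lesion-free images stay honest; pooled-count aggregation is
available to sidestep the issue entirely.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_curve

CLASSES = ("normal", "cancer")


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Decimal half-up rounding (display convention for metric tables)."""
    if not np.isfinite(x):
        return float(x)
    # absorb float representation error (1.711/2 = 0.85549999...) before the
    # decimal half-up step
    d = Decimal(repr(float(x))).quantize(Decimal(1).scaleb(-12))
    return float(d.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def swapped(self) -> "ConfusionCounts":
        """Counts with the positive class complemented."""
        return ConfusionCounts(tp=self.tn, tn=self.tp, fp=self.fn, fn=self.fp)


@dataclass(frozen=True)
class ClassMetrics:
    accuracy: float
    iou: float
    precision: float
    recall: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {"accuracy": self.accuracy, "iou": self.iou,
                "precision": self.precision, "recall": self.recall, "f1": self.f1}


def confusion_counts(pred, truth, positive_class: str = "cancer") -> ConfusionCounts:
    """Tabulate pixel counts with the named class as positive.

    ``"cancer"`` treats lesion foreground as positive; ``"normal"`` treats
    background as positive (both masks complemented).
    """
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if positive_class not in CLASSES:
        raise ValueError(f"positive_class must be one of {CLASSES}")
    if positive_class == "normal":
        pred, truth = ~pred, ~truth
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def metrics_from_counts(c: ConfusionCounts) -> ClassMetrics:
    """Accuracy, IoU, precision, recall and F1 from pixel counts."""
    if c.total == 0:
        raise ValueError("no pixels evaluated")
    return ClassMetrics(
        accuracy=(c.tp + c.tn) / c.total,
        iou=_ratio(c.tp, c.tp + c.fp + c.fn),
        precision=_ratio(c.tp, c.tp + c.fp),
        recall=_ratio(c.tp, c.tp + c.fn),
        f1=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
    )


def metrics_from_precision_recall(p: float, r: float) -> tuple[float, float]:
    """(F1, IoU) from precision and recall.

    F1 is the harmonic mean 2pr/(p+r); IoU follows from the identity
    IoU = F1 / (2 - F1) = pr / (p + r - pr).
    """
    if p == 0 and r == 0:
        return float("nan"), float("nan")
    if not (0 <= p <= 1 and 0 <= r <= 1):
        raise ValueError("precision and recall must be in [0,1]")
    f1 = 2 * p * r / (p + r)
    iou = p * r / (p + r - p * r)
    return f1, iou


@dataclass(frozen=True)
class MetricReport:
    per_class: dict[str, ClassMetrics]

    def macro(self) -> dict[str, float]:
        return macro_average(self)

    def rounded(self, ndigits: int = 3) -> dict:
        out = {cls: {k: round_half_up(v, ndigits) for k, v in m.as_dict().items()}
               for cls, m in self.per_class.items()}
        out["average"] = {k: round_half_up(v, ndigits) for k, v in self.macro().items()}
        return out


def evaluate_masks(pred, truth) -> MetricReport:
    """Two-class (normal/cancer) metric report for one pair or pooled pairs."""
    return MetricReport(per_class={
        cls: metrics_from_counts(confusion_counts(pred, truth, cls))
        for cls in CLASSES
    })


def macro_average(report: MetricReport) -> dict[str, float]:
    """Arithmetic mean of each metric over the normal and cancer classes."""
    missing = [c for c in CLASSES if c not in report.per_class]
    if missing:
        raise ValueError(f"class missing from report: {missing}")
    out = {}
    for key in ("accuracy", "iou", "precision", "recall", "f1"):
        vals = [getattr(report.per_class[c], key) for c in CLASSES]
        out[key] = float(np.mean(vals))  # NaN propagates: flagged, not hidden
    return out


def pixel_roc_pr(prob_maps, truths, per_image: bool = False):
    """ROC and PR curves over lesion probability at the pixel level.

    Pixels are pooled across images by default (deterministic; set
    ``per_image`` to average the per-image areas instead).  Returns a dict
    with curve points, trapezoidal AUROC, and step-interpolated AUPRC.
    """
    if isinstance(prob_maps, np.ndarray) and prob_maps.ndim == 2:
        prob_maps, truths = [prob_maps], [truths]
    pairs = []
    for p, t in zip(prob_maps, truths, strict=True):
        p, t = np.asarray(p, dtype=float), np.asarray(t).astype(bool)
        if p.shape != t.shape:
            raise ValueError("probability map and truth shapes differ")
        pairs.append((p.ravel(), t.ravel()))

    if per_image:
        aurocs, auprcs = [], []
        for p, t in pairs:
            if t.all() or not t.any():
                raise ValueError("single-class truth in an image")
            aurocs.append(_auroc(p, t))
            auprcs.append(average_precision_score(t, p))
        return {"auroc": float(np.mean(aurocs)), "auprc": float(np.mean(auprcs)),
                "per_image_auroc": aurocs, "per_image_auprc": auprcs}

    scores = np.concatenate([p for p, _ in pairs])
    labels = np.concatenate([t for _, t in pairs])
    if labels.all() or not labels.any():
        raise ValueError("need at least one positive and one negative pixel")
    fpr, tpr, roc_thr = roc_curve(labels, scores)
    prec, rec, pr_thr = precision_recall_curve(labels, scores)
    return {
        "auroc": float(np.trapezoid(tpr, fpr)),
        "auprc": float(average_precision_score(labels, scores)),
        "roc": {"fpr": fpr, "tpr": tpr, "thresholds": roc_thr},
        "pr": {"precision": prec, "recall": rec, "thresholds": pr_thr},
    }


def _auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    fpr, tpr, _ = roc_curve(labels, scores)
    return float(np.trapezoid(tpr, fpr))
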