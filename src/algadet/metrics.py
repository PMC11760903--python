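"""Object-detection evaluation: P/R, PR curves, AP, mAP, ROC and AUC.

Definitions used throughout:

* ``P = TP / (TP + FP)`` and ``R = TP / (TP + FN)`` from greedy matching of
  predictions to ground truths at an IoU threshold;
* ``AP`` is the area under the precision-recall curve, integrated with the
  monotone (right-envelope) all-points interpolation;
* ``mAP`` is the class-mean of AP; ``map50`` at IoU 0.5, ``map5095``
  averaged over the ten thresholds 0.50, 0.55, ..., 0.95;
* ``AUC`` is the pairwise-indicator form: over all positive/negative score
  pairs, count 1 when the positive outranks the negative, 0.5 on ties,
  divided by ``P * N`` — numerically identical to the area under the ROC
  curve swept over score thresholds.

The matching protocol (not a metric definition, but required to produce
TP/FP flags for a detector) is the standard greedy assignment: predictions
are visited in descending confidence and claim the highest-IoU unmatched
ground truth of the same class on the same image, provided IoU >= threshold.
Each ground truth is matched at most once; leftover ground truths are false
negatives.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .boxes import Box
from .losses import iou as box_iou

__all__ = [
    "DetectionRecord",
    "EvalResult",
    "UndefinedAUCError",
    "COCO_THRESHOLDS",
    "match_detections",
    "precision_recall",
    "average_precision",
    "mean_ap",
    "roc_auc",
    "plot_pr_curves",
    "plot_roc_curves",
]

#: the ten-threshold IoU grid 0.50:0.05:0.95
COCO_THRESHOLDS = tuple(np.round(np.linspace(0.5, 0.95, 10), 2))


class UndefinedAUCError(ValueError):
    """AUC requires at least one positive and one negative score."""


@dataclass(frozen=True)
class DetectionRecord:
    """One detection (or ground-truth instance, with score 1)."""

    image_id: str
    class_id: int
    score: float
    box: Box

    def __post_init__(self):
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must lie in [0, 1], got {self.score}")


@dataclass
class EvalResult:
    """Full evaluation report of a prediction set against ground truth."""

    per_class_ap: dict[int, float]
    map50: float
    map5095: float
    precision: float
    recall: float
    pr_curves: dict[int, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    roc: dict[int, np.ndarray] = field(default_factory=dict)
    auc: dict[int, float] = field(default_factory=dict)
    ap_per_threshold: dict[float, dict[int, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_class_ap": {str(k): float(v) for k, v in self.per_class_ap.items()},
            "map50": float(self.map50),
            "map5095": float(self.map5095),
            "precision": float(self.precision),
            "recall": float(self.recall),
            "auc": {str(k): (None if np.isnan(v) else float(v)) for k, v in self.auc.items()},
            "ap_per_threshold": {
                f"{t:.2f}": {str(k): float(v) for k, v in aps.items()}
                for t, aps in self.ap_per_threshold.items()
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def match_detections(preds, gts, iou_threshold: float = 0.5):
    """Greedy TP/FP assignment of predictions to ground truths.

    Parameters
    ----------
    preds, gts : sequence of DetectionRecord
    iou_threshold : float in (0, 1)

    Returns
    -------
    flags : list of bool, aligned with the input prediction order
        True where the prediction is a true positive.
    n_fn : int
        Number of ground truths left unmatched.
    """
    if not 0.0 < iou_threshold < 1.0:
        raise ValueError(f"iou_threshold must lie in (0, 1), got {iou_threshold}")
    # stable order: descending score, input order breaking ties
    order = sorted(range(len(preds)), key=lambda i: -preds[i].score)
    gt_by_key: dict[tuple, list[int]] = {}
    for j, g in enumerate(gts):
        gt_by_key.setdefault((g.image_id, g.class_id), []).append(j)
    matched = [False] * len(gts)
    flags = [False] * len(preds)
    for i in order:
        p = preds[i]
        best_j, best_iou = -1, 0.0
        for j in gt_by_key.get((p.image_id, p.class_id), ()):
            if matched[j]:
                continue
            ov = box_iou(p.box, gts[j].box)
            if ov > best_iou:
                best_j, best_iou = j, ov
        if best_j >= 0 and best_iou >= iou_threshold:
            matched[best_j] = True
            flags[i] = True
    return flags, matched.count(False)


def precision_recall(tp: int, fp: int, fn: int) -> tuple[float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN); 0 by convention on empty denominators."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    p = tp / (tp + fp) if tp + fp > 0 else 0.0
    r = tp / (tp + fn) if tp + fn > 0 else 0.0
    return p, r


def average_precision(scored_flags, n_gt: int, method: str = "interp") -> float:
    """Area under the precision-recall curve.

    Parameters
    ----------
    scored_flags : sequence of (score, is_tp)
    n_gt : int
        Number of ground-truth instances (recall denominator).
    method : {"interp", "11point"}
        ``"interp"`` integrates the monotone precision envelope over all
        recall points (the continuous form of the integral definition);
        ``"11point"`` samples the envelope at recalls 0.0, 0.1, ..., 1.0.
    """
    if n_gt < 0:
        raise ValueError("n_gt must be non-negative")
    if method not in ("interp", "11point"):
        raise ValueError(f"unknown AP method {method!r}")
    if n_gt == 0 or not scored_flags:
        return 0.0
    order = sorted(range(len(scored_flags)), key=lambda i: -scored_flags[i][0])
    flags = np.array([bool(scored_flags[i][1]) for i in order])
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(~flags)
    recall = tp_cum / n_gt
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1)
    # monotone non-increasing precision envelope
    env = np.maximum.accumulate(precision[::-1])[::-1]
    if method == "11point":
        return float(np.mean([env[recall >= r].max() if np.any(recall >= r) else 0.0
                              for r in np.linspace(0, 1, 11)]))
    # integrate: sum precision-envelope over recall increments
    prev_r = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_r) * env))


def _pr_curve(scored_flags, n_gt: int):
    if n_gt == 0 or not scored_flags:
        return np.array([0.0]), np.array([0.0])
    order = sorted(range(len(scored_flags)), key=lambda i: -scored_flags[i][0])
    flags = np.array([bool(scored_flags[i][1]) for i in order])
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(~flags)
    recall = tp_cum / n_gt
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1)
    return recall, precision


def mean_ap(preds, gts, thresholds=COCO_THRESHOLDS, ap_method: str = "interp") -> EvalResult:
    """Evaluate a prediction set: per-class AP, mAP@0.5, mAP@[0.5:0.95], ROC/AUC.

    Classes with neither ground truth nor predictions are excluded from the
    class means.  The headline ``precision``/``recall`` are micro-averaged
    counts at IoU 0.5 over all supplied predictions.  Per-class ROC/AUC use
    a one-vs-rest construction from detection scores at IoU 0.5: matched
    detections are the positive score set, unmatched the negative set (an
    evaluator protocol for detectors, which have no natural negative class);
    AUC is NaN for classes where either set is empty.
    """
    thresholds = tuple(float(t) for t in thresholds)
    if not thresholds:
        raise ValueError("thresholds must be non-empty")
    classes = sorted({r.class_id for r in preds} | {r.class_id for r in gts})
    ap_per_threshold: dict[float, dict[int, float]] = {t: {} for t in thresholds}
    pr_curves: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    roc: dict[int, np.ndarray] = {}
    auc: dict[int, float] = {}
    per_class_ap: dict[int, float] = {}

    tau0 = 0.5 if 0.5 in thresholds else thresholds[0]
    total_tp = total_fp = total_fn = 0

    for c in classes:
        c_preds = [p for p in preds if p.class_id == c]
        c_gts = [g for g in gts if g.class_id == c]
        for t in thresholds:
            flags, _ = match_detections(c_preds, c_gts, t)
            ap = average_precision(
                [(p.score, f) for p, f in zip(c_preds, flags)], len(c_gts), ap_method
            )
            ap_per_threshold[t][c] = ap
        flags0, fn0 = match_detections(c_preds, c_gts, tau0)
        tp0 = sum(flags0)
        total_tp += tp0
        total_fp += len(flags0) - tp0
        total_fn += fn0
        per_class_ap[c] = ap_per_threshold[tau0][c]
        pr_curves[c] = _pr_curve([(p.score, f) for p, f in zip(c_preds, flags0)], len(c_gts))
        pos = [p.score for p, f in zip(c_preds, flags0) if f]
        neg = [p.score for p, f in zip(c_preds, flags0) if not f]
        if pos and neg:
            points, area = roc_auc(pos, neg)
            roc[c] = points
            auc[c] = area
        else:
            roc[c] = np.zeros((0, 2))
            auc[c] = float("nan")

    p, r = precision_recall(total_tp, total_fp, total_fn)
    map50 = float(np.mean([ap_per_threshold[tau0][c] for c in classes])) if classes else 0.0
    map5095 = (
        float(np.mean([np.mean([ap_per_threshold[t][c] for t in thresholds]) for c in classes]))
        if classes
        else 0.0
    )
    return EvalResult(
        per_class_ap=per_class_ap,
        map50=map50,
        map5095=map5095,
        precision=p,
        recall=r,
        pr_curves=pr_curves,
        roc=roc,
        auc=auc,
        ap_per_threshold=ap_per_threshold,
    )


def roc_auc(pos_scores, neg_scores):
    """ROC points and pairwise-indicator AUC.

    AUC is the mean over all positive/negative pairs of the indicator that
    the positive score outranks the negative one (ties count 0.5).  The ROC
    points come from a sweep over score thresholds: each point is
    (FPR, TPR) = (fraction of negatives >= t, fraction of positives >= t),
    anchored at (0, 0) and (1, 1).  The trapezoidal area under these points
    equals the pairwise AUC.
    """
    pos = np.asarray(list(pos_scores), dtype=np.float64)
    neg = np.asarray(list(neg_scores), dtype=np.float64)
    if pos.size == 0 or neg.size == 0:
        raise UndefinedAUCError("AUC needs at least one positive and one negative score")
    diff = pos[:, None] - neg[None, :]
    indicator = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    auc = float(indicator.sum() / (pos.size * neg.size))

    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    tpr = [(pos >= t).mean() for t in thresholds]
    fpr = [(neg >= t).mean() for t in thresholds]
    points = np.vstack([[0.0, 0.0], np.column_stack([fpr, tpr]), [1.0, 1.0]])
    return points, auc


def plot_pr_curves(result: EvalResult, path, class_names=None) -> None:
    """Write per-class precision-recall curves to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    for c, (recall, precision) in sorted(result.pr_curves.items()):
        name = class_names[c] if class_names else f"class {c}"
        ax.plot(recall, precision, label=f"{name} (AP={result.per_class_ap[c]:.3f})")
    ax.set_xlabel("Recall")
    ax.set_ylabel("Precision")
    ax.set_xlim(0, 1.02)
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=7)
    ax.set_title(f"PR curves (mAP@0.5 = {result.map50:.3f})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_roc_curves(result: EvalResult, path, class_names=None) -> None:
    """Write per-class ROC curves to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    for c, points in sorted(result.roc.items()):
        if points.size == 0:
            continue
        name = class_names[c] if class_names else f"class {c}"
        ax.plot(points[:, 0], points[:, 1], label=f"{name} (AUC={result.auc[c]:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="chance")
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(fontsize=7)
    ax.set_title("ROC curves (one-vs-rest detection scores)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
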