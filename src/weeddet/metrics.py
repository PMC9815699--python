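"""Detection evaluation: IoU matching, precision/recall/F1, AP, mAP.

Conventions:

* Matching is greedy in descending confidence: each detection takes the
  unmatched ground-truth box of highest IoU if that IoU reaches the
  threshold, otherwise it is a false positive.  Ground truth is matched at
  most once; unmatched ground truth counts as false negatives.
* AP is the area under the precision-envelope/recall curve with all-points
  interpolation (the exact discretization of the continuous integral
  definition); mAP is the plain mean of per-class APs, and the 0.5:0.95
  variant averages mAP over the ten IoU thresholds 0.50, 0.55, ..., 0.95
  inclusive.
* Confidence ties are broken by detection input order (stable sort).
* A class with zero ground-truth boxes has no defined AP; it is reported as
  ``None`` and excluded from the mAP mean rather than counted as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

RANGE_THRESHOLDS = tuple(np.round(np.arange(0.5, 0.96, 0.05), 2))  # 0.5 .. 0.95


def iou(box_a, box_b) -> float:
    """Intersection over union of two (x1, y1, x2, y2) boxes; 0 for
    degenerate zero-area boxes by convention."""
    ax1, ay1, ax2, ay2 = box_a
    bx1, by1, bx2, by2 = box_b
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
    return inter / union if union > 0 else 0.0


@dataclass
class MatchResult:
    """Per-detection TP/FP flags (in descending-confidence order) plus the
    false-negative count, for one image and one class at one IoU threshold."""

    tp_flags: np.ndarray
    confidences: np.ndarray
    n_fn: int
    iou_threshold: float

    @property
    def n_tp(self) -> int:
        return int(self.tp_flags.sum())

    @property
    def n_fp(self) -> int:
        return int(len(self.tp_flags) - self.tp_flags.sum())


def match(detections, truths, iou_threshold: float = 0.5) -> MatchResult:
    """Greedily match one image's single-class detections against truth.

    ``detections``: sequence of (confidence, x1, y1, x2, y2);
    ``truths``: sequence of (x1, y1, x2, y2).
    """
    dets = np.asarray([list(d) for d in detections], dtype=float).reshape(-1, 5)
    order = np.argsort(-dets[:, 0], kind="stable")
    dets = dets[order]
    used = np.zeros(len(truths), dtype=bool)
    tp = np.zeros(len(dets), dtype=bool)
    for i, det in enumerate(dets):
        best_iou, best_j = 0.0, -1
        for j, t in enumerate(truths):
            if used[j]:
                continue
            v = iou(det[1:], t)
            if v > best_iou:
                best_iou, best_j = v, j
        if best_j >= 0 and best_iou >= iou_threshold:
            tp[i] = True
            used[best_j] = True
    return MatchResult(tp_flags=tp, confidences=dets[:, 0],
                       n_fn=int((~used).sum()), iou_threshold=iou_threshold)


def precision_recall_f1(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall and F1 from raw counts; undefined terms are 0."""
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return precision, recall, f1


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def average_precision(tp_flags: np.ndarray, confidences: np.ndarray,
                      n_truth: int) -> float | None:
    """All-points interpolated AP from pooled per-detection TP flags.

    Detections from all images are pooled, sorted by descending confidence
    (stable), and swept to a precision-recall curve; AP is the area under the
    running-maximum precision envelope.  Returns ``None`` when there is no
    ground truth for the class (AP undefined).
    """
    if n_truth == 0:
        return None
    tp_flags = np.asarray(tp_flags, dtype=bool)
    confidences = np.asarray(confidences, dtype=float)
    if len(tp_flags) == 0:
        return 0.0
    order = np.argsort(-confidences, kind="stable")
    tp = tp_flags[order].astype(float)
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(1.0 - tp)
    recall = cum_tp / n_truth
    precision = cum_tp / (cum_tp + cum_fp)
    # precision envelope and all-points area
    r = np.concatenate(([0.0], recall, [recall[-1]]))
    p = np.concatenate(([1.0], precision, [0.0]))
    for i in range(len(p) - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    idx = np.nonzero(np.diff(r) > 0)[0]
    return float(np.sum((r[idx + 1] - r[idx]) * p[idx + 1]))


def mean_ap(per_class_aps) -> float | None:
    """Arithmetic mean of the defined per-class APs (``None`` entries are
    classes without ground truth and are excluded)."""
    defined = [a for a in per_class_aps if a is not None]
    if not defined:
        return None
    return float(np.mean(defined))


@dataclass
class MetricsReport:
    """Evaluation summary over a detection corpus."""

    per_class: dict[int, dict] = field(default_factory=dict)
    map50: float | None = None
    map50_95: float | None = None
    iou_threshold: float = 0.5

    def row(self, cls: int, key: str):
        return self.per_class.get(cls, {}).get(key)

    def to_text(self, class_names=("crop", "weed")) -> str:
        lines = ["class\tprecision\trecall\tf1\tap"]
        for cls, vals in sorted(self.per_class.items()):
            name = class_names[cls] if cls < len(class_names) else str(cls)
            ap = vals["ap"]
            lines.append(
                f"{name}\t{vals['precision']:.3f}\t{vals['recall']:.3f}"
                f"\t{vals['f1']:.3f}\t{'NA' if ap is None else f'{ap:.3f}'}")
        lines.append(f"mAP@0.5\t{'NA' if self.map50 is None else f'{self.map50:.3f}'}")
        lines.append(
            f"mAP@0.5:0.95\t"
            f"{'NA' if self.map50_95 is None else f'{self.map50_95:.3f}'}")
        return "\n".join(lines)


def _pool_class(detections_by_image: dict, truths_by_image: dict, cls: int,
                iou_threshold: float):
    flags, confs, n_truth, n_fn = [], [], 0, 0
    for image_id in sorted(set(detections_by_image) | set(truths_by_image)):
        dets = [d for d in detections_by_image.get(image_id, [])
                if int(d[0]) == cls]
        trs = [t[1:] for t in truths_by_image.get(image_id, [])
               if int(t[0]) == cls]
        n_truth += len(trs)
        m = match([d[1:] for d in dets], trs, iou_threshold)
        flags.append(m.tp_flags)
        confs.append(m.confidences)
        n_fn += m.n_fn
    flags = np.concatenate(flags) if flags else np.zeros(0, dtype=bool)
    confs = np.concatenate(confs) if confs else np.zeros(0)
    return flags, confs, n_truth, n_fn


def evaluate(detections_by_image: dict, truths_by_image: dict,
             classes=(0, 1), iou_threshold: float = 0.5) -> MetricsReport:
    """Full evaluation of a corpus.

    ``detections_by_image``: image_id -> list of
    (class_id, confidence, x1, y1, x2, y2); ``truths_by_image``: image_id ->
    list of (class_id, x1, y1, x2, y2), all in pixels.
    """
    report = MetricsReport(iou_threshold=iou_threshold)
    aps50 = {}
    for cls in classes:
        flags, confs, n_truth, n_fn = _pool_class(
            detections_by_image, truths_by_image, cls, iou_threshold)
        tp, fp = int(flags.sum()), int(len(flags) - flags.sum())
        p, r, f1 = precision_recall_f1(tp, fp, n_fn)
        ap = average_precision(flags, confs, n_truth)
        aps50[cls] = ap
        report.per_class[cls] = {
            "precision": p, "recall": r, "f1": f1, "ap": ap,
            "tp": tp, "fp": fp, "fn": n_fn, "n_truth": n_truth,
        }
    report.map50 = mean_ap(aps50.values())

    range_maps = []
    for thr in RANGE_THRESHOLDS:
        aps = []
        for cls in classes:
            flags, confs, n_truth, _ = _pool_class(
                detections_by_image, truths_by_image, cls, float(thr))
            aps.append(average_precision(flags, confs, n_truth))
        m = mean_ap(aps)
        if m is not None:
            range_maps.append(m)
    report.map50_95 = float(np.mean(range_maps)) if range_maps else None
    return report


def map_range(detections_by_image: dict, truths_by_image: dict,
              classes=(0, 1)) -> float | None:
    """mAP averaged over IoU thresholds 0.5:0.05:0.95 (both ends included)."""
    return evaluate(detections_by_image, truths_by_image, classes).map50_95
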