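"""Detection evaluation: PR curves, AP and mAP at an IoU threshold.

Matching follows the de-facto VOC/COCO rule: within each image and class,
detections are taken in descending confidence; a detection is a true
positive (TP) when its best-IoU *unmatched* GT box exceeds the threshold
(default 0.5), which then consumes that GT; otherwise it is a false positive
(FP).  GT boxes never consumed are false negatives (FN).  From the pooled
per-class detections,

    P = TP / (TP + FP),    R = TP / (TP + FN),

AP is the area under the precision envelope over recall (all-point
interpolation — the literal integral of P(R)), and mAP is the unweighted
mean of per-class APs.  "Mean recall" is the unweighted mean of the final
per-class recalls.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .boxes import iou_xyxy
from .voc import AnnotatedImage

log = logging.getLogger(__name__)

__all__ = [
    "Detection",
    "PRCurve",
    "EvaluationReport",
    "match_detections",
    "pr_curve",
    "average_precision",
    "evaluate",
    "read_detections_csv",
    "write_detections_csv",
]


@dataclass(frozen=True)
class Detection:
    class_id: int
    box: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


@dataclass
class MatchResult:
    """Confidence-ordered TP/FP labels per class, plus FN counts."""

    labels: dict[int, list[tuple[float, bool]]]  # class -> [(confidence, is_tp)]
    n_gt: dict[int, int]

    def tallies(self, class_id: int) -> tuple[int, int, int]:
        tp = sum(is_tp for _, is_tp in self.labels.get(class_id, []))
        fp = len(self.labels.get(class_id, [])) - tp
        fn = self.n_gt.get(class_id, 0) - tp
        return tp, fp, fn


def match_detections(
    detections: Mapping[str, Sequence[Detection]],
    ground_truth: Iterable[AnnotatedImage],
    iou_threshold: float = 0.5,
) -> MatchResult:
    """Greedy per-image, per-class matching of detections to GT boxes.

    ``detections`` maps image path to its detection list.  Ties in
    confidence break on input order; ties in IoU break on the lower GT
    index, so reports are deterministic.
    """
    labels: dict[int, list[tuple[float, bool]]] = {}
    n_gt: dict[int, int] = {}
    for img in ground_truth:
        gt_by_class: dict[int, list] = {}
        for obj in img.objects:
            gt_by_class.setdefault(obj.class_id, []).append(obj.box.as_tuple())
            n_gt[obj.class_id] = n_gt.get(obj.class_id, 0) + 1
        dets = detections.get(img.image_path, ())
        by_class: dict[int, list[Detection]] = {}
        for det in dets:
            by_class.setdefault(det.class_id, []).append(det)
        for cid, class_dets in by_class.items():
            gts = gt_by_class.get(cid, [])
            used = [False] * len(gts)
            order = sorted(range(len(class_dets)), key=lambda i: -class_dets[i].confidence)
            for i in order:
                det = class_dets[i]
                best_iou, best_j = 0.0, -1
                for j, gt in enumerate(gts):
                    if used[j]:
                        continue
                    v = iou_xyxy(det.box, gt)
                    if v > best_iou:
                        best_iou, best_j = v, j
                is_tp = best_iou > iou_threshold
                if is_tp:
                    used[best_j] = True
                labels.setdefault(cid, []).append((det.confidence, is_tp))
    return MatchResult(labels=labels, n_gt=n_gt)


@dataclass
class PRCurve:
    """Precision/recall points in descending-confidence order."""

    precision: np.ndarray
    recall: np.ndarray
    tp: int
    fp: int
    fn: int

    @property
    def final_recall(self) -> float:
        return float(self.recall[-1]) if len(self.recall) else 0.0


def pr_curve(labeled: Sequence[tuple[float, bool]], n_gt: int) -> PRCurve:
    """Cumulative PR curve from pooled ``(confidence, is_tp)`` labels.

    Confidence ties break pessimistically (FP before TP) so the curve is a
    pure function of the label multiset, independent of image order.
    """
    order = sorted(range(len(labeled)), key=lambda i: (-labeled[i][0], labeled[i][1]))
    flags = np.array([labeled[i][1] for i in order], dtype=bool)
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(~flags)
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1)
    recall = tp_cum / n_gt if n_gt > 0 else np.zeros_like(tp_cum, dtype=float)
    tp = int(tp_cum[-1]) if len(flags) else 0
    return PRCurve(precision, recall, tp=tp, fp=len(flags) - tp, fn=n_gt - tp)


def average_precision(curve: PRCurve) -> float:
    """Area under the precision envelope over recall (all-point rule)."""
    if len(curve.recall) == 0:
        return 0.0
    r = np.concatenate([[0.0], curve.recall, [curve.recall[-1]]])
    p = np.concatenate([[0.0], curve.precision, [0.0]])
    # envelope: precision at recall r is the max precision at any recall >= r
    for i in range(len(p) - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    idx = np.where(r[1:] != r[:-1])[0]
    return float(np.sum((r[idx + 1] - r[idx]) * p[idx + 1]))


@dataclass
class EvaluationReport:
    per_class_ap: dict[int, float]
    per_class_recall: dict[int, float]
    per_class_curve: dict[int, PRCurve] = field(repr=False, default_factory=dict)
    iou_threshold: float = 0.5

    @property
    def map(self) -> float:
        if not self.per_class_ap:
            return 0.0
        return float(np.mean(list(self.per_class_ap.values())))

    @property
    def mean_recall(self) -> float:
        if not self.per_class_recall:
            return 0.0
        return float(np.mean(list(self.per_class_recall.values())))

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["class_id", "AP", "R", "TP", "FP", "FN"])
            for cid in sorted(self.per_class_ap):
                c = self.per_class_curve[cid]
                w.writerow(
                    [cid, f"{self.per_class_ap[cid]:.4f}",
                     f"{self.per_class_recall[cid]:.4f}", c.tp, c.fp, c.fn]
                )
            w.writerow(["mean", f"{self.map:.4f}", f"{self.mean_recall:.4f}", "", "", ""])


def evaluate(
    detections: Mapping[str, Sequence[Detection]],
    ground_truth: Sequence[AnnotatedImage],
    classes: Sequence[int],
    iou_threshold: float = 0.5,
) -> EvaluationReport:
    """Full report: per-class AP and final recall, mAP and mean recall.

    A class with neither GT nor detections carries no information and is
    excluded from the means with a warning.
    """
    if not classes:
        raise ValueError("classes must be non-empty")
    result = match_detections(detections, ground_truth, iou_threshold)
    per_ap: dict[int, float] = {}
    per_r: dict[int, float] = {}
    curves: dict[int, PRCurve] = {}
    for cid in classes:
        labeled = result.labels.get(cid, [])
        n_gt = result.n_gt.get(cid, 0)
        if not labeled and n_gt == 0:
            log.warning("class %d has no GT and no detections; excluded from means", cid)
            continue
        curve = pr_curve(labeled, n_gt)
        curves[cid] = curve
        per_ap[cid] = average_precision(curve)
        per_r[cid] = curve.final_recall
    return EvaluationReport(per_ap, per_r, curves, iou_threshold)


# ---------------------------------------------------------------------------
# Detection file I/O (CSV: image, class_id, xmin, ymin, xmax, ymax, confidence)


def write_detections_csv(
    detections: Mapping[str, Sequence[Detection]], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["image", "class_id", "xmin", "ymin", "xmax", "ymax", "confidence"])
        for image in sorted(detections):
            for d in detections[image]:
                w.writerow([image, d.class_id, *d.box, d.confidence])


def read_detections_csv(path: str | Path) -> dict[str, list[Detection]]:
    out: dict[str, list[Detection]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.setdefault(row["image"], []).append(
                Detection(
                    class_id=int(row["class_id"]),
                    box=(
                        float(row["xmin"]), float(row["ymin"]),
                        float(row["xmax"]), float(row["ymax"]),
                    ),
                    confidence=float(row["confidence"]),
                )
            )
    return out
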