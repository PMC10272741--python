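"""Quantitative evaluation: pixel errors, detection scores and box losses.

Pixel level: NWP (wrongly extracted road pixels), NRP (ROI pixel count) and
their ratio RBP = 100 * NWP / NRP.  Detection level: greedy
confidence-ordered matching at an IoU threshold, precision / recall / F1,
all-point-interpolated average precision and mAP.  The CIoU and binary
cross-entropy losses used by single-stage detectors are provided as
standalone evaluative functions.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .image import ROAD, Mask

__all__ = [
    "Box",
    "Detection",
    "PixelEval",
    "DetEval",
    "count_nwp",
    "rbp",
    "pixel_eval",
    "box_iou",
    "match_detections",
    "precision_recall_f1",
    "f1_score",
    "average_precision",
    "map_over_classes",
    "evaluate_detections",
    "ciou_loss",
    "bce_loss",
    "promotion_ratio",
]


@dataclass(frozen=True)
class Box:
    """Axis-aligned box in pixel coordinates (closed real intervals)."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(f"degenerate box {self}")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0)

    def to_dict(self) -> dict:
        return {"x_min": self.x_min, "y_min": self.y_min, "x_max": self.x_max, "y_max": self.y_max}


@dataclass(frozen=True)
class Detection:
    """A detector output: box, confidence in [0, 1], class label."""

    box: Box
    confidence: float
    label: str = "fruit"

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")

    def to_dict(self) -> dict:
        d = self.box.to_dict()
        d.update({"confidence": self.confidence, "label": self.label})
        return d


@dataclass
class PixelEval:
    nwp: int
    nrp: int
    rbp: float


@dataclass
class DetEval:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    ap: float
    map: float


def count_nwp(pred_road: Mask, gt_road: Mask, *, symmetric: bool = False) -> int:
    """Wrongly extracted pixels: road in the prediction but not in truth.

    With ``symmetric=True`` missed road pixels are added as well.
    """
    if pred_road.shape != gt_road.shape:
        raise ValueError(f"shape mismatch: {pred_road.shape} vs {gt_road.shape}")
    if pred_road.polarity != ROAD or gt_road.polarity != ROAD:
        raise ValueError("count_nwp expects road-polarity masks")
    p, g = pred_road.as_bool(), gt_road.as_bool()
    wrong = int(np.count_nonzero(p & ~g))
    if symmetric:
        wrong += int(np.count_nonzero(~p & g))
    return wrong


def rbp(nwp: float, nrp: float) -> float:
    """Wrong-pixel ratio 100 * NWP / NRP, in percent."""
    if nrp <= 0:
        raise ValueError("NRP must be positive")
    if not 0 <= nwp <= nrp:
        raise ValueError("NWP must lie in [0, NRP]")
    return 100.0 * nwp / nrp


def pixel_eval(pred_road: Mask, gt_road: Mask, *, symmetric: bool = False) -> PixelEval:
    """NWP / NRP / RBP for a predicted mask against ground truth."""
    nwp = count_nwp(pred_road, gt_road, symmetric=symmetric)
    nrp = int(np.prod(pred_road.shape))
    return PixelEval(nwp=nwp, nrp=nrp, rbp=rbp(nwp, nrp))


def box_iou(a: Box, b: Box) -> float:
    """Intersection over union; 0 for disjoint boxes."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def _greedy_match(preds: list[Detection], gts: list[Box], iou_thresh: float) -> list[bool]:
    """Per-prediction TP flags, confidence-descending greedy matching.

    Ties in confidence keep input order (stable sort); each ground-truth box
    matches at most one prediction; a prediction matches the unclaimed box
    of highest IoU provided IoU >= iou_thresh.
    """
    order = sorted(range(len(preds)), key=lambda i: -preds[i].confidence)
    claimed = [False] * len(gts)
    flags = [False] * len(preds)
    for i in order:
        best_j, best_iou = -1, iou_thresh
        for j, gt in enumerate(gts):
            if claimed[j]:
                continue
            iou = box_iou(preds[i].box, gt)
            if iou > best_iou or (iou == best_iou and best_j < 0 and iou >= iou_thresh):
                best_j, best_iou = j, iou
        if best_j >= 0 and best_iou >= iou_thresh:
            claimed[best_j] = True
            flags[i] = True
    return flags


def match_detections(preds: list[Detection], gts: list[Box], iou_thresh: float = 0.5) -> tuple[int, int, int]:
    """(tp, fp, fn) under greedy confidence-ordered matching."""
    if not 0.0 < iou_thresh < 1.0:
        raise ValueError("iou_thresh must be in (0, 1)")
    flags = _greedy_match(preds, gts, iou_thresh)
    tp = sum(flags)
    return tp, len(preds) - tp, len(gts) - tp


def precision_recall_f1(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """P = tp/(tp+fp), R = tp/(tp+fn), F1 their harmonic mean (0 if undefined)."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    p = tp / (tp + fp) if tp + fp > 0 else 0.0
    r = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2.0 * p * r / (p + r) if p + r > 0 else 0.0
    return p, r, f1


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean 2PR/(P+R) of precision and recall rates (0 if both 0)."""
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise ValueError("precision and recall must lie in [0, 1]")
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def average_precision(preds: list[Detection], gts: list[Box], iou_thresh: float = 0.5) -> float:
    """Area under the all-point interpolated precision-recall curve.

    Returns NaN when there are no ground-truth boxes (undefined).
    """
    if not gts:
        return math.nan
    if not preds:
        return 0.0
    order = sorted(range(len(preds)), key=lambda i: -preds[i].confidence)
    flags = _greedy_match(preds, gts, iou_thresh)
    tp_flags = np.array([flags[i] for i in order], dtype=float)
    tp_cum = np.cumsum(tp_flags)
    fp_cum = np.cumsum(1.0 - tp_flags)
    recall = tp_cum / len(gts)
    precision = tp_cum / (tp_cum + fp_cum)

    mrec = np.concatenate(([0.0], recall, [recall[-1]]))
    mpre = np.concatenate(([0.0], precision, [0.0]))
    for i in range(len(mpre) - 2, -1, -1):  # precision envelope from the right
        mpre[i] = max(mpre[i], mpre[i + 1])
    idx = np.where(mrec[1:] != mrec[:-1])[0]
    return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))


def map_over_classes(per_class_ap: dict[str, float]) -> float:
    """Mean AP over classes; with one class this is that class's AP."""
    if not per_class_ap:
        raise ValueError("no classes")
    vals = list(per_class_ap.values())
    return float(np.mean(vals))


def evaluate_detections(preds: list[Detection], gts: list[Box], iou_thresh: float = 0.5) -> DetEval:
    """Counts plus P/R/F1/AP/mAP for a single-class detection task."""
    tp, fp, fn = match_detections(preds, gts, iou_thresh)
    p, r, f1 = precision_recall_f1(tp, fp, fn)
    ap = average_precision(preds, gts, iou_thresh)
    return DetEval(tp=tp, fp=fp, fn=fn, precision=p, recall=r, f1=f1, ap=ap,
                   map=ap)


def ciou_loss(pred: Box, gt: Box) -> float:
    """Complete-IoU loss: 1 - IoU + centre-distance and aspect-ratio penalties.

    L = 1 - IoU + rho^2/c_d^2 + alpha*upsilon with
    upsilon = (4/pi^2) * (arctan(w_g/h_g) - arctan(w_p/h_p))^2 and
    alpha = upsilon / ((1 - IoU) + upsilon).
    """
    iou = box_iou(pred, gt)
    (cx_p, cy_p), (cx_g, cy_g) = pred.center, gt.center
    rho2 = (cx_p - cx_g) ** 2 + (cy_p - cy_g) ** 2
    cw = max(pred.x_max, gt.x_max) - min(pred.x_min, gt.x_min)
    ch = max(pred.y_max, gt.y_max) - min(pred.y_min, gt.y_min)
    c2 = cw**2 + ch**2
    upsilon = (4.0 / math.pi**2) * (math.atan(gt.width / gt.height) - math.atan(pred.width / pred.height)) ** 2
    denom = (1.0 - iou) + upsilon
    alpha = upsilon / denom if denom > 0 else 0.0
    return (1.0 - iou) + rho2 / c2 + alpha * upsilon


def bce_loss(confidences, labels, eps: float = 1e-7) -> float:
    """Mean binary cross-entropy, confidences clamped to [eps, 1 - eps]."""
    x = np.asarray(confidences, dtype=float)
    y = np.asarray(labels, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    if x.shape != y.shape:
        raise ValueError("confidences and labels must have the same length")
    x = np.clip(x, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(x) + (1.0 - y) * np.log(1.0 - x)))


def promotion_ratio(v_w: float, v_n: float) -> float:
    """Relative improvement (v_w - v_n) / v_n of a with-pipeline value."""
    if v_n == 0:
        raise ValueError("reference value must be non-zero")
    return (v_w - v_n) / v_n
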