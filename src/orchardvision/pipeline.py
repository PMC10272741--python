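"""Synchronous road extraction and roadside fruit detection.

One pass produces both the road mask and the fruit detections: the frame is
preprocessed, the road is extracted, and a pluggable detector runs on the
preprocessed region of interest.  Detections lying (almost) entirely on the
road surface are discarded — fruit hangs beside the road, not on it.  A
colour-blob detector tuned to dark purple grape clusters ships as the
reference detector so the fusion logic is testable without a trained
network; any callable mapping an RGB image to a detection list plugs in.
"""
from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from skimage import measure

from .image import Mask, as_rgb, rgb_to_hsv8
from .metrics import Box, Detection, promotion_ratio
from .preprocess import PreprocessConfig
from .roadseg import RoadResult, SegConfig, extract_road

__all__ = [
    "DetectorContract",
    "SyncResult",
    "hue_blob_detector",
    "make_hue_blob_detector",
    "synchronous_detect",
    "compare_protocol",
]

#: a detector is any callable RGB image -> list of Detection
DetectorContract = Callable[[np.ndarray], list[Detection]]


@dataclass
class SyncResult:
    """Joint output of one synchronous pass (ROI coordinate frame)."""

    road: RoadResult
    detections: list[Detection]
    timing: dict[str, float]
    fruit_present: bool


def hue_blob_detector(
    img: np.ndarray,
    hue_range: tuple[float, float] = (118.0, 172.0),
    sat_min: float = 30.0,
    min_area: int = 120,
) -> list[Detection]:
    """Detect dark purple blobs (grape clusters) by hue thresholding.

    Pixels with hue inside ``hue_range`` (8-bit scale, H in [0, 180)) and
    saturation >= ``sat_min`` are grouped into connected components;
    components of at least ``min_area`` px become detections with
    confidence = component area / largest component area.
    """
    if not (0 <= hue_range[0] <= hue_range[1] < 180):
        raise ValueError("hue_range must lie within [0, 180)")
    if sat_min < 0 or min_area <= 0:
        raise ValueError("sat_min must be >= 0 and min_area positive")
    hsv = rgb_to_hsv8(as_rgb(img))
    mask = (hsv[..., 0] >= hue_range[0]) & (hsv[..., 0] <= hue_range[1]) & (hsv[..., 1] >= sat_min)
    labels = measure.label(mask, connectivity=2)
    regions = [r for r in measure.regionprops(labels) if r.area >= min_area]
    if not regions:
        return []
    max_area = max(r.area for r in regions)
    dets = []
    for r in regions:
        y0, x0, y1, x1 = r.bbox
        dets.append(Detection(Box(float(x0), float(y0), float(x1), float(y1)), float(r.area / max_area)))
    dets.sort(key=lambda d: -d.confidence)
    return dets


def make_hue_blob_detector(**kwargs) -> DetectorContract:
    """Bind :func:`hue_blob_detector` parameters into a detector callable."""
    return lambda img: hue_blob_detector(img, **kwargs)


def _road_overlap_fraction(box: Box, road: Mask) -> float:
    h, w = road.shape
    x0 = int(np.clip(np.floor(box.x_min), 0, w))
    x1 = int(np.clip(np.ceil(box.x_max), 0, w))
    y0 = int(np.clip(np.floor(box.y_min), 0, h))
    y1 = int(np.clip(np.ceil(box.y_max), 0, h))
    if x1 <= x0 or y1 <= y0:
        return 0.0
    patch = road.as_bool()[y0:y1, x0:x1]
    return float(patch.mean())


def synchronous_detect(
    img: np.ndarray,
    detector: DetectorContract,
    pre_cfg: PreprocessConfig | None = None,
    seg_cfg: SegConfig | None = None,
    *,
    road_overlap_drop: float = 0.9,
    mask_road: bool = True,
    enhance: bool = True,
) -> SyncResult:
    """Preprocess, extract the road, then detect fruit beside it.

    The detector sees the preprocessed ROI image with the extracted road
    surface blacked out (the road result is the input to recognition);
    ``mask_road=False`` feeds the plain ROI instead, exposed because the
    two readings trade speed against context.  Detections with more than
    ``road_overlap_drop`` of their area on the final road mask are dropped
    either way.
    """
    t0 = time.perf_counter()
    road = extract_road(img, pre_cfg, seg_cfg, enhance=enhance)
    t1 = time.perf_counter()
    det_input = road.enhanced
    if mask_road:
        det_input = det_input.copy()
        det_input[road.road_mask.as_bool()] = 0
    raw_dets = detector(det_input)
    t2 = time.perf_counter()
    h, w = road.road_mask.shape
    kept = []
    for d in raw_dets:
        b = d.box
        if b.x_max <= 0 or b.y_max <= 0 or b.x_min >= w or b.y_min >= h:
            continue
        if _road_overlap_fraction(b, road.road_mask) >= road_overlap_drop:
            continue
        kept.append(d)
    return SyncResult(
        road=road,
        detections=kept,
        timing={"road_extraction": t1 - t0, "detection": t2 - t1, "total": t2 - t0},
        fruit_present=bool(kept),
    )


def compare_protocol(
    images: Sequence[np.ndarray],
    detector: DetectorContract,
    pre_cfg: PreprocessConfig | None = None,
    seg_cfg: SegConfig | None = None,
    *,
    enhance: bool = True,
    iterations: int = 1,
) -> dict:
    """With/without-pipeline comparison on a batch of frames.

    The detector runs once directly on each raw frame ("without") and once
    through the synchronous pipeline ("with").  The report gives total
    detection counts, mean per-frame wall time, and promotion ratios for
    count and speed (frames per second).  ``enhance=False`` ablates the
    enhancement stages; the report marks the stage as absent.
    """
    if len(images) == 0:
        raise ValueError("empty image list")
    count_n = count_w = 0
    time_n = time_w = 0.0
    for img in images:
        t0 = time.perf_counter()
        for _ in range(iterations):
            dets_raw = detector(as_rgb(img))
        time_n += (time.perf_counter() - t0) / iterations
        count_n += len(dets_raw)
        t0 = time.perf_counter()
        res = synchronous_detect(img, detector, pre_cfg, seg_cfg, enhance=enhance)
        time_w += time.perf_counter() - t0
        count_w += len(res.detections)

    n = len(images)
    mean_t_n, mean_t_w = time_n / n, time_w / n
    report = {
        "n_images": n,
        "count_without": count_n,
        "count_with": count_w,
        "mean_time_without_s": mean_t_n,
        "mean_time_with_s": mean_t_w,
        "stages": {"preprocess_enhancement": bool(enhance), "road_extraction": True},
        "promotion_ratio_count": promotion_ratio(count_w, count_n) if count_n else None,
        "promotion_ratio_speed": promotion_ratio(1.0 / mean_t_w, 1.0 / mean_t_n) if mean_t_w > 0 and mean_t_n > 0 else None,
    }
    return report
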