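"""Dual-space unstructured road extraction.

Road pixels are what is left after removing vegetation found by two
independent routes: an HSV green-range mask and a binarised
green-dominance gray factor (1.84*G - B - R, an excess-green variant tuned
for vineyard soil).  The two vegetation masks are fused by intersecting
their road complements, then morphology keeps a single bottom-anchored
road component.  Two classic single-route baselines (saturation + Otsu and
ExG + Otsu) are provided for comparison.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure, morphology

from .image import ROAD, VEGETATION, Mask, as_rgb, rgb_to_hsv8
from .preprocess import PreprocessConfig, crop_roi, preprocess

__all__ = [
    "SegConfig",
    "RoadResult",
    "green_mask_hsv",
    "optimized_gray",
    "binarize_gray",
    "fuse_masks",
    "morph_clean",
    "extract_road",
    "otsu_threshold",
    "baseline_s_otsu",
    "baseline_exg_otsu",
]


@dataclass
class SegConfig:
    """Segmentation thresholds.

    HSV ranges (8-bit convention, H in [0,180)) bound the green vegetation
    band; ``green_coeff`` is the G weight of the optimised gray factor and
    ``t_b`` its binarisation threshold.  Morphology uses a disk footprint of
    diameter ``morph_kernel`` and drops components below
    ``min_component_area``.
    """

    h_range: tuple[float, float] = (35.0, 77.0)
    s_range: tuple[float, float] = (43.0, 255.0)
    v_range: tuple[float, float] = (46.0, 255.0)
    green_coeff: float = 1.84
    t_b: float = 10.0
    morph_kernel: int = 15
    min_component_area: int = 500

    def validate(self) -> None:
        for lo, hi, top in ((*self.h_range, 180.0), (*self.s_range, 255.0), (*self.v_range, 255.0)):
            if not (0.0 <= lo <= hi <= top):
                raise ValueError("HSV ranges must lie within channel bounds")
        if self.morph_kernel <= 0 or self.morph_kernel % 2 == 0:
            raise ValueError("morph_kernel must be odd and positive")
        if self.min_component_area < 0:
            raise ValueError("min_component_area must be non-negative")


@dataclass
class RoadResult:
    """Final road mask plus every intermediate, for audit."""

    road_mask: Mask
    hsv_road: Mask
    gray_road: Mask
    fused: Mask
    gray_image: np.ndarray
    road_found: bool
    enhanced: np.ndarray  # the image the masks were computed on (ROI frame)


def green_mask_hsv(img: np.ndarray, cfg: SegConfig | None = None) -> Mask:
    """255 where the pixel falls inside the green HSV box (inclusive ends)."""
    cfg = cfg or SegConfig()
    cfg.validate()
    hsv = rgb_to_hsv8(as_rgb(img))
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    inside = (
        (h >= cfg.h_range[0]) & (h <= cfg.h_range[1])
        & (s >= cfg.s_range[0]) & (s <= cfg.s_range[1])
        & (v >= cfg.v_range[0]) & (v <= cfg.v_range[1])
    )
    return Mask(np.where(inside, 255, 0).astype(np.uint8), VEGETATION)


def optimized_gray(img: np.ndarray, green_coeff: float = 1.84) -> np.ndarray:
    """Signed gray factor ``green_coeff*G - B - R`` (no clipping)."""
    f = as_rgb(img).astype(float)
    return green_coeff * f[..., 1] - f[..., 2] - f[..., 0]


def binarize_gray(gray: np.ndarray, t_b: float = 10.0) -> Mask:
    """0 where gray <= t_b (road candidate), 255 where gray > t_b (plant)."""
    g = np.asarray(gray, dtype=float)
    return Mask(np.where(g > t_b, 255, 0).astype(np.uint8), VEGETATION)


def fuse_masks(hsv_mask: Mask, gray_mask: Mask) -> Mask:
    """Road candidates = pixels vegetation in neither input mask."""
    if hsv_mask.shape != gray_mask.shape:
        raise ValueError(f"shape mismatch: {hsv_mask.shape} vs {gray_mask.shape}")
    if hsv_mask.polarity != VEGETATION or gray_mask.polarity != VEGETATION:
        raise ValueError("fuse_masks expects two vegetation-polarity masks")
    road = ~(hsv_mask.as_bool() | gray_mask.as_bool())
    return Mask(np.where(road, 255, 0).astype(np.uint8), ROAD)


def morph_clean(mask: Mask, cfg: SegConfig | None = None) -> Mask:
    """Closing + opening, small-component removal, keep the bottom road blob.

    Closing runs first so that salt-noise holes in the road candidate
    region are sealed before opening prunes thin spurs and speckle islands
    (opening-first erases a hole-riddled road outright).  Output is
    constrained to the input's support (cleaning never invents road
    pixels).  The surviving component must touch the bottom image row (the
    road starts at the robot's feet); if none does the result is empty,
    which callers read via ``Mask.is_empty``.
    """
    cfg = cfg or SegConfig()
    cfg.validate()
    if mask.polarity != ROAD:
        raise ValueError("morph_clean expects a road-polarity mask")
    src = mask.as_bool()
    if not src.any():
        return Mask(np.zeros(mask.shape, np.uint8), ROAD)

    footprint = morphology.disk(cfg.morph_kernel // 2)
    closed = morphology.closing(src.astype(np.uint8), footprint)
    cleaned = morphology.opening(closed, footprint).astype(bool)

    labels = measure.label(cleaned, connectivity=2)
    best, best_area = 0, 0
    bottom = labels[-1, :]
    for region in measure.regionprops(labels):
        if region.area < cfg.min_component_area:
            continue
        if not np.any(bottom == region.label):
            continue
        if region.area > best_area:
            best, best_area = region.label, region.area
    if best == 0:
        return Mask(np.zeros(mask.shape, np.uint8), ROAD)
    kept = (labels == best) & src
    return Mask(np.where(kept, 255, 0).astype(np.uint8), ROAD)


def extract_road(
    img: np.ndarray,
    pre_cfg: PreprocessConfig | None = None,
    seg_cfg: SegConfig | None = None,
    *,
    enhance: bool = True,
) -> RoadResult:
    """Full road extraction: preprocess, dual-space masks, fusion, cleanup.

    With ``enhance=False`` only the ROI crop of the preprocessing chain is
    applied (the ablation arm): segmentation then runs on the raw crop.
    """
    pre_cfg = pre_cfg or PreprocessConfig()
    seg_cfg = seg_cfg or SegConfig()
    pre_cfg.validate()
    seg_cfg.validate()
    work = preprocess(img, pre_cfg) if enhance else crop_roi(img, pre_cfg.roi_fraction)

    veg_hsv = green_mask_hsv(work, seg_cfg)
    gray = optimized_gray(work, seg_cfg.green_coeff)
    veg_gray = binarize_gray(gray, seg_cfg.t_b)
    fused = fuse_masks(veg_hsv, veg_gray)
    road = morph_clean(fused, seg_cfg)
    return RoadResult(
        road_mask=road,
        hsv_road=veg_hsv.complement(ROAD),
        gray_road=veg_gray.complement(ROAD),
        fused=fused,
        gray_image=gray,
        road_found=not road.is_empty,
        enhanced=work,
    )


def otsu_threshold(gray: np.ndarray) -> float:
    """Between-class-variance-maximising threshold of a real-valued map.

    The input is min-max scaled onto [0, 255], histogrammed into 256 unit
    bins, and the integer split maximising the between-class variance is
    mapped back to the input scale.  Values <= the returned threshold form
    the low class.
    """
    g = np.asarray(gray, dtype=float)
    lo, hi = float(g.min()), float(g.max())
    if hi - lo < 1e-12:
        raise ValueError("Otsu threshold undefined for a constant input")
    scaled = np.rint((g - lo) / (hi - lo) * 255.0)
    hist = np.bincount(scaled.astype(int).ravel(), minlength=256).astype(float)
    total = hist.sum()
    prob = hist / total
    omega = np.cumsum(prob)
    mu = np.cumsum(prob * np.arange(256))
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    t = int(np.argmax(sigma_b[:-1]))  # split below 255 so both classes exist
    return lo + t / 255.0 * (hi - lo)


def baseline_s_otsu(img: np.ndarray) -> Mask:
    """Saturation-channel Otsu baseline; low-saturation side labelled road."""
    s = rgb_to_hsv8(as_rgb(img))[..., 1]
    t = otsu_threshold(s)
    return Mask(np.where(s <= t, 255, 0).astype(np.uint8), ROAD)


def baseline_exg_otsu(img: np.ndarray) -> Mask:
    """Excess-green (2G - R - B) Otsu baseline; low-ExG side labelled road."""
    f = as_rgb(img).astype(float)
    exg = 2.0 * f[..., 1] - f[..., 0] - f[..., 2]
    t = otsu_threshold(exg)
    return Mask(np.where(exg <= t, 255, 0).astype(np.uint8), ROAD)
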