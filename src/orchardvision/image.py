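"""Image containers, colour-space conversions and PNG/JPEG I/O.

All images are H x W x 3 uint8 RGB arrays.  HSV follows the 8-bit machine
vision convention: H in [0, 180), S and V in [0, 255].  Published colour
thresholds for plant/soil segmentation are stated on this scale, so it is
used throughout rather than the unit-interval scale.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage import color as _skcolor

#: polarity labels for binary masks
VEGETATION = "vegetation"
ROAD = "road"

# Rec. 709 luma weights, matching skimage.color.rgb2gray.
GRAY_WEIGHTS = (0.2125, 0.7154, 0.0721)


def as_rgb(img: np.ndarray) -> np.ndarray:
    """Validate and return an H x W x 3 uint8 RGB image.

    Accepts any integer or float array already in [0, 255].
    """
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 RGB image, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError("empty image")
    if arr.dtype != np.uint8:
        a = np.asarray(arr, dtype=float)
        if a.min() < 0 or a.max() > 255:
            raise ValueError("channel values outside [0, 255]")
        arr = np.rint(a).astype(np.uint8)
    return arr


def rgb_to_hsv8(img: np.ndarray) -> np.ndarray:
    """RGB uint8 -> float HSV with H in [0, 180), S and V in [0, 255]."""
    hsv = _skcolor.rgb2hsv(as_rgb(img))
    out = np.empty_like(hsv)
    out[..., 0] = hsv[..., 0] * 180.0
    out[..., 1] = hsv[..., 1] * 255.0
    out[..., 2] = hsv[..., 2] * 255.0
    return out


def hsv8_to_rgb(hsv: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_hsv8`; returns uint8 RGB."""
    h = np.asarray(hsv, dtype=float)
    unit = np.empty_like(h)
    unit[..., 0] = np.mod(h[..., 0] / 180.0, 1.0)
    unit[..., 1] = np.clip(h[..., 1] / 255.0, 0.0, 1.0)
    unit[..., 2] = np.clip(h[..., 2] / 255.0, 0.0, 1.0)
    rgb = _skcolor.hsv2rgb(unit) * 255.0
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


def to_gray(img: np.ndarray) -> np.ndarray:
    """Luma conversion to a float grayscale image on the [0, 255] scale."""
    return _skcolor.rgb2gray(as_rgb(img)) * 255.0


@dataclass
class Mask:
    """Binary H x W mask with values in {0, 255}.

    ``polarity`` records what 255 means ("vegetation" or "road") so that
    fusion and cleaning steps can refuse semantically mismatched inputs.
    """

    pixels: np.ndarray
    polarity: str

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {arr.shape}")
        if arr.dtype != np.uint8:
            arr = arr.astype(np.uint8)
        vals = np.unique(arr)
        if not np.isin(vals, (0, 255)).all():
            raise ValueError("mask values must be 0 or 255")
        if self.polarity not in (VEGETATION, ROAD):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        self.pixels = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def is_empty(self) -> bool:
        """True when no pixel is set; for road masks this is the no-road flag."""
        return not bool(self.pixels.any())

    def as_bool(self) -> np.ndarray:
        return self.pixels > 0

    def area(self) -> int:
        return int(np.count_nonzero(self.pixels))

    def complement(self, polarity: str) -> "Mask":
        return Mask(255 - self.pixels, polarity)


def mask_iou(a: Mask, b: Mask) -> float:
    """Intersection over union of two masks (same polarity expected)."""
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    pa, pb = a.as_bool(), b.as_bool()
    union = np.count_nonzero(pa | pb)
    if union == 0:
        return 1.0
    return float(np.count_nonzero(pa & pb) / union)


def read_image(path: str | Path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[..., :3]
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    return as_rgb(arr)


def write_image(path: str | Path, img: np.ndarray) -> None:
    iio.imwrite(path, as_rgb(img))


def read_mask(path: str | Path, polarity: str = ROAD) -> Mask:
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    arr = np.where(np.asarray(arr) > 127, 255, 0).astype(np.uint8)
    return Mask(arr, polarity)


def write_mask(path: str | Path, mask: Mask) -> None:
    iio.imwrite(path, mask.pixels)
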