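"""Seeded generator of vineyard-like scenes with ground truth.

Each scene contains, from top to bottom: a bright sky band, green vine rows
flanking a central soil road trapezoid with low-frequency irregular edges,
dark purple grape clusters hanging on the vine rows, elliptical cast
shadows on the road, and additive Gaussian pixel noise.  The colours are
chosen so that vine pixels fall inside the green HSV segmentation box and
soil pixels have a negative green-dominance gray factor, which is what the
road extractor relies on in real footage.  Ground truth is the road mask,
the grape-cluster bounding boxes and the shadow support.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .image import ROAD, Mask, hsv8_to_rgb, write_image, write_mask
from .metrics import Box

__all__ = ["SceneSpec", "SceneTruth", "generate_scene", "generate_dataset"]


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene.

    The defaults mirror the study conditions: 1024 x 473 frames, a road
    narrowing toward the horizon, moderate shadowing, a handful of grape
    clusters per frame and mild sensor noise (sd 5 intensity units).
    """

    width: int = 1024
    height: int = 473
    road_top_width_frac: float = 0.18
    road_bottom_width_frac: float = 0.55
    soil_rgb_mean: tuple[int, int, int] = (120, 100, 78)
    vine_rgb_mean: tuple[int, int, int] = (62, 128, 54)
    grape_rgb_mean: tuple[int, int, int] = (88, 42, 108)
    sky_rgb_mean: tuple[int, int, int] = (205, 218, 235)
    shadow_count: int = 3
    shadow_darkening: float = 0.5
    grape_cluster_count: int = 6
    #: fraction of clusters hung at the road edge, overhanging the road the
    #: way real fruit overhangs the row boundary
    grape_edge_fraction: float = 0.5
    #: bare-soil gaps in the foliage near the road edge (leaf gaps / cavities)
    vine_gap_count: int = 4
    noise_sd: float = 5.0
    edge_jitter: float = 18.0
    seed: int = 0

    def validate(self) -> None:
        if self.width < 32 or self.height < 32:
            raise ValueError("scene must be at least 32 x 32")
        for frac in (self.road_top_width_frac, self.road_bottom_width_frac):
            if not 0.0 < frac < 1.0:
                raise ValueError("road width fractions must be in (0, 1)")
        for col in (self.soil_rgb_mean, self.vine_rgb_mean, self.grape_rgb_mean, self.sky_rgb_mean):
            if len(col) != 3 or min(col) < 0 or max(col) > 255:
                raise ValueError(f"colour {col} outside [0, 255]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 < self.shadow_darkening <= 1.0:
            raise ValueError("shadow_darkening must be in (0, 1]")
        if self.shadow_count < 0 or self.grape_cluster_count < 0 or self.vine_gap_count < 0:
            raise ValueError("counts must be non-negative")
        if not 0.0 <= self.grape_edge_fraction <= 1.0:
            raise ValueError("grape_edge_fraction must be in [0, 1]")


@dataclass
class SceneTruth:
    """A rendered scene bundled with its ground truth."""

    image: np.ndarray
    road_mask_gt: Mask
    fruit_boxes_gt: list[Box]
    shadow_mask_gt: Mask
    spec: SceneSpec


def _road_edges(spec: SceneSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-row left/right road edge columns and the horizon row."""
    h, w = spec.height, spec.width
    horizon = h // 6
    rows = np.arange(h)
    t = np.clip((rows - horizon) / max(h - 1 - horizon, 1), 0.0, 1.0)
    half = (spec.road_top_width_frac + t * (spec.road_bottom_width_frac - spec.road_top_width_frac)) * w / 2.0
    # low-frequency lateral jitter of the centreline and of each edge
    center = w / 2.0 + ndimage.gaussian_filter1d(rng.normal(0, 1, h), 40) * spec.edge_jitter
    jl = ndimage.gaussian_filter1d(rng.normal(0, 1, h), 12) * spec.edge_jitter * 0.5
    jr = ndimage.gaussian_filter1d(rng.normal(0, 1, h), 12) * spec.edge_jitter * 0.5
    left = np.clip(center - half + jl, 1, w - 2)
    right = np.clip(center + half + jr, 1, w - 2)
    bad = right <= left + 2
    right[bad] = left[bad] + 3
    return left, right, horizon


def _paint_vines(img: np.ndarray, region: np.ndarray, rng: np.random.Generator) -> None:
    """Fill ``region`` with green foliage sampled inside the HSV green box."""
    h, w, _ = img.shape
    hue = rng.uniform(40.0, 72.0, (h, w))
    sat = rng.uniform(115.0, 200.0, (h, w))
    val = np.clip(rng.uniform(70.0, 165.0, (h, w)) + ndimage.gaussian_filter(rng.normal(0, 25, (h, w)), 8), 60.0, 170.0)
    hsv = np.stack([hue, sat, val], axis=-1)
    rgb = hsv8_to_rgb(hsv)
    img[region] = rgb[region]


def _paint_soil(img: np.ndarray, region: np.ndarray, spec: SceneSpec, rng: np.random.Generator) -> None:
    """Soil tones: a common low-frequency brightness field plus small
    independent per-channel texture, keeping the gray factor safely <= 0."""
    h, w, _ = img.shape
    base = np.array(spec.soil_rgb_mean, dtype=float)
    common = ndimage.gaussian_filter(rng.normal(0, 18, (h, w)), 10)
    soil = base[None, None, :] + common[..., None] + rng.normal(0, 3, (h, w, 3))
    img[region] = np.clip(soil, 0, 255)[region]


def _ellipse(h: int, w: int, cy: float, cx: float, ry: float, rx: float, angle: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    ca, sa = np.cos(angle), np.sin(angle)
    u = (xx - cx) * ca + (yy - cy) * sa
    v = -(xx - cx) * sa + (yy - cy) * ca
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def generate_scene(spec: SceneSpec | None = None) -> SceneTruth:
    """Render one scene deterministically from ``spec.seed``."""
    spec = spec or SceneSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    img = np.zeros((h, w, 3), dtype=float)

    left, right, horizon = _road_edges(spec, rng)
    cols = np.arange(w)
    road = np.zeros((h, w), dtype=bool)
    road[horizon:, :] = (cols[None, :] >= left[horizon:, None]) & (cols[None, :] <= right[horizon:, None])

    # sky with a vertical gradient
    sky = np.array(spec.sky_rgb_mean, dtype=float)
    grad = np.linspace(1.0, 0.92, horizon)[:, None, None] if horizon > 0 else None
    if horizon > 0:
        img[:horizon] = np.clip(sky[None, None, :] * grad, 0, 255)

    below = np.zeros((h, w), dtype=bool)
    below[horizon:] = True
    vines = below & ~road
    _paint_vines(img, vines, rng)
    _paint_soil(img, road, spec, rng)

    # bare-soil leaf gaps in the foliage close to the road edge
    for _ in range(spec.vine_gap_count):
        gy = rng.uniform(horizon + 0.15 * (h - horizon), h - 5)
        row = int(gy)
        side = rng.integers(0, 2)
        off = rng.uniform(0.0, 0.04) * w
        gx = left[row] - off if side == 0 else right[row] + off
        gap = _ellipse(h, w, gy, gx, rng.uniform(0.015, 0.035) * h, rng.uniform(0.01, 0.025) * w, rng.uniform(-0.5, 0.5))
        gap &= vines
        _paint_soil(img, gap, spec, rng)

    # grape clusters on the vine bands, never centred on the road; a share
    # of them hangs at the road edge, overhanging the road surface
    boxes: list[Box] = []
    attempts, placed = 0, 0
    centers: list[tuple[float, float]] = []
    while placed < spec.grape_cluster_count and attempts < spec.grape_cluster_count * 60:
        attempts += 1
        y = rng.uniform(horizon + 0.1 * h, h - 0.15 * h)
        side = rng.integers(0, 2)
        row = int(y)
        margin = 0.03 * w
        at_edge = placed < spec.grape_edge_fraction * spec.grape_cluster_count
        if at_edge:
            off = rng.uniform(0.002, 0.02) * w
            x = left[row] - off if side == 0 else right[row] + off
            if x < margin or x > w - margin:
                continue
        else:
            if side == 0:
                x_lo, x_hi = margin, left[row] - 2 * margin
            else:
                x_lo, x_hi = right[row] + 2 * margin, w - margin
            if x_hi - x_lo < 0.04 * w:
                continue
            x = rng.uniform(x_lo, x_hi)
        if any((x - cx) ** 2 + (y - cy) ** 2 < (0.09 * w) ** 2 for cx, cy in centers):
            continue
        # a cluster is a bundle of overlapping berry ellipses
        n_berries = int(rng.integers(6, 12))
        cluster = np.zeros((h, w), dtype=bool)
        for _ in range(n_berries):
            by = y + rng.normal(0, 0.018 * h)
            bx = x + rng.normal(0, 0.010 * w)
            r = rng.uniform(0.006, 0.011) * w
            cluster |= _ellipse(h, w, by, bx, r * rng.uniform(0.8, 1.2), r, rng.uniform(0, np.pi))
        cluster &= below
        if not cluster.any():
            continue
        gc = np.array(spec.grape_rgb_mean, dtype=float)
        shade = rng.normal(0, 8, (h, w))
        for c in range(3):
            img[..., c][cluster] = np.clip(gc[c] + shade[cluster] + rng.normal(0, 4), 0, 255)
        ys, xs = np.nonzero(cluster)
        boxes.append(Box(float(xs.min()), float(ys.min()), float(xs.max() + 1), float(ys.max() + 1)))
        centers.append((x, y))
        placed += 1

    # cast shadows on the road (multiplicative darkening)
    shadow = np.zeros((h, w), dtype=bool)
    for _ in range(spec.shadow_count):
        sy = rng.uniform(horizon + 0.2 * (h - horizon), h - 5)
        row = int(sy)
        sx = rng.uniform(left[row], right[row])
        e = _ellipse(h, w, sy, sx, rng.uniform(0.03, 0.07) * h, rng.uniform(0.06, 0.16) * w, rng.uniform(-0.4, 0.4))
        shadow |= e & road
    img[shadow] *= spec.shadow_darkening

    if spec.noise_sd > 0:
        img += rng.normal(0, spec.noise_sd, img.shape)
    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    return SceneTruth(
        image=image,
        road_mask_gt=Mask(np.where(road, 255, 0).astype(np.uint8), ROAD),
        fruit_boxes_gt=boxes,
        shadow_mask_gt=Mask(np.where(shadow, 255, 0).astype(np.uint8), ROAD),
        spec=spec,
    )


def generate_dataset(n: int, spec: SceneSpec | None = None, out_dir: str | Path | None = None) -> list[SceneTruth]:
    """Generate ``n`` scenes with seeds ``spec.seed + i``; optionally write
    image/mask/box triples (PNG, PNG, JSON) to ``out_dir``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = spec or SceneSpec()
    scenes = [generate_scene(replace(spec, seed=spec.seed + i)) for i in range(n)]
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i, scene in enumerate(scenes):
            stem = f"scene_{i:03d}"
            write_image(out / f"{stem}_image.png", scene.image)
            write_mask(out / f"{stem}_road.png", scene.road_mask_gt)
            with open(out / f"{stem}_boxes.json", "w") as fh:
                json.dump([b.to_dict() for b in scene.fruit_boxes_gt], fh, indent=1)
    return scenes
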