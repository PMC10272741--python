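"""Internal smoothing kernels: bilateral grid and large-sigma Gaussian.

The bilateral filter follows the bilateral-grid formulation (splat the image
into a coarse space x intensity grid, Gaussian-blur the grid, slice back with
trilinear interpolation).  It reproduces the edge-preserving behaviour of a
direct bilateral filter at a cost independent of the kernel diameter, which
matters because the road pipeline uses a 60 px pixel-domain diameter on
1024 x 473 frames.
"""
from __future__ import annotations

import numpy as np
from scipy import ndimage


def gaussian_blur(channel: np.ndarray, sigma: float) -> np.ndarray:
    """2-D Gaussian blur; large sigmas run on a decimated copy.

    For sigma above 20 px a direct separable convolution is wasteful (kernel
    length ~8*sigma); the channel is decimated by ~sigma/10, blurred at the
    reduced sigma and linearly resampled back.  The approximation error is
    far below the quantisation step for the smooth surfaces involved.
    """
    ch = np.asarray(channel, dtype=float)
    if sigma <= 0:
        return ch.copy()
    if sigma <= 20:
        return ndimage.gaussian_filter(ch, sigma, mode="nearest")
    factor = max(1, int(sigma / 10.0))
    small = ch[::factor, ::factor]
    small = ndimage.gaussian_filter(small, sigma / factor, mode="nearest")
    out = ndimage.zoom(small, (ch.shape[0] / small.shape[0], ch.shape[1] / small.shape[1]), order=1, mode="nearest")
    # zoom can be off by a pixel; crop/pad to the exact shape
    out = out[: ch.shape[0], : ch.shape[1]]
    if out.shape != ch.shape:
        out = np.pad(out, ((0, ch.shape[0] - out.shape[0]), (0, ch.shape[1] - out.shape[1])), mode="edge")
    return out


def _bilateral_channel(ch: np.ndarray, sigma_spatial: float, sigma_range: float) -> np.ndarray:
    h, w = ch.shape
    ss = max(float(sigma_spatial), 1.0)
    sr = max(float(sigma_range), 1.0)
    lo, hi = float(ch.min()), float(ch.max())
    if hi - lo < 1e-12:
        return ch.copy()

    gy = int(np.ceil(h / ss)) + 3
    gx = int(np.ceil(w / ss)) + 3
    gz = int(np.ceil((hi - lo) / sr)) + 3

    yy, xx = np.mgrid[0:h, 0:w]
    iy = np.rint(yy / ss).astype(int) + 1
    ix = np.rint(xx / ss).astype(int) + 1
    iz = np.rint((ch - lo) / sr).astype(int) + 1

    flat = (iy * gx + ix) * gz + iz
    wsum = np.bincount(flat.ravel(), minlength=gy * gx * gz).astype(float)
    vsum = np.bincount(flat.ravel(), weights=ch.ravel(), minlength=gy * gx * gz)
    wgrid = wsum.reshape(gy, gx, gz)
    vgrid = vsum.reshape(gy, gx, gz)

    wgrid = ndimage.gaussian_filter(wgrid, 1.0, mode="constant")
    vgrid = ndimage.gaussian_filter(vgrid, 1.0, mode="constant")

    coords = np.stack([yy / ss + 1, xx / ss + 1, (ch - lo) / sr + 1])
    num = ndimage.map_coordinates(vgrid, coords, order=1, mode="nearest")
    den = ndimage.map_coordinates(wgrid, coords, order=1, mode="nearest")
    out = np.where(den > 1e-12, num / np.maximum(den, 1e-12), ch)
    return out


def bilateral_filter(img: np.ndarray, d: float, sigma_space: float, sigma_intensity: float) -> np.ndarray:
    """Edge-preserving smoothing of an RGB uint8 image, channel-wise.

    ``d`` is the pixel-domain diameter: the effective spatial sigma is
    capped at d/2 because a direct bilateral kernel is truncated at that
    radius regardless of how large ``sigma_space`` is.
    """
    if d <= 0 or sigma_space <= 0 or sigma_intensity <= 0:
        raise ValueError("bilateral parameters must be positive")
    arr = np.asarray(img, dtype=float)
    sigma_sp = min(float(sigma_space), float(d) / 2.0)
    out = np.empty_like(arr)
    for c in range(arr.shape[2]):
        out[..., c] = _bilateral_channel(arr[..., c], sigma_sp, sigma_intensity)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)
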