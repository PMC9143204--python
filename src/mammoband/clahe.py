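"""Contrast-limited adaptive histogram equalization (CLAHE).

Implements the standard tile-grid algorithm on 8-bit images: the image is
divided into ``grid x grid`` tiles, each tile's 256-bin histogram is
clipped at ``clip_limit * tile_area / 256`` counts with the excess
redistributed uniformly, a per-tile equalization LUT is built from the
clipped CDF, and every pixel is mapped through a bilinear blend of the
four nearest tile LUTs.  The clip limit is on the conventional
"multiples of the uniform histogram level" scale, so values like 1.11 or
20 are meaningful; ``clip_limit -> 0`` approaches the identity transform
and large values approach plain per-tile histogram equalization.

A tile with zero dynamic range maps through the identity LUT, making any
constant region an exact fixed point of the transform.
"""

from __future__ import annotations

import numpy as np

from .image_io import GrayImage, as_gray_image

__all__ = ["clahe"]

_NBINS = 256


def _tile_lut(tile: np.ndarray, clip_limit: float) -> np.ndarray:
    area = tile.size
    hist = np.bincount(tile.ravel(), minlength=_NBINS).astype(np.int64)
    lo = int(tile.min())
    hi = int(tile.max())
    if lo == hi:
        return np.arange(_NBINS, dtype=np.uint8)
    clip = max(1, int(clip_limit * area / _NBINS))
    excess = int(np.maximum(hist - clip, 0).sum())
    if excess > 0:
        hist = np.minimum(hist, clip)
        hist += excess // _NBINS
        rem = excess % _NBINS
        if rem:
            hist[:rem] += 1
    cdf = np.cumsum(hist)
    lut = np.floor(cdf * ((_NBINS - 1.0) / area) + 0.5)
    return np.clip(lut, 0, 255).astype(np.uint8)


def _axis_coords(n: int, grid: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel (lower tile index, upper tile index, upper weight)."""
    bounds = np.linspace(0, n, grid + 1).astype(np.int64)
    centers = (bounds[:-1] + bounds[1:] - 1) / 2.0
    p = np.arange(n, dtype=np.float64)
    j = np.searchsorted(centers, p, side="right") - 1
    i0 = np.clip(j, 0, grid - 1)
    i1 = np.clip(j + 1, 0, grid - 1)
    denom = centers[i1] - centers[i0]
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(denom > 0, (p - centers[i0]) / np.where(denom > 0, denom, 1.0), 0.0)
    return i0, i1, np.clip(w, 0.0, 1.0)


def clahe(img: GrayImage, clip_limit: float, grid: int = 8) -> GrayImage:
    """Apply CLAHE to an 8-bit image.

    Parameters
    ----------
    img
        2-D uint8 image.
    clip_limit
        Positive histogram clip limit; the per-tile clip in counts is
        ``clip_limit * tile_area / 256`` (at least 1).
    grid
        Number of tiles per axis (default 8, i.e. an 8x8 grid).  The grid
        is reduced automatically for images smaller than the grid.
    """
    img = as_gray_image(img)
    if clip_limit <= 0:
        raise ValueError("clip_limit must be positive")
    h, w = img.shape
    gy = max(1, min(grid, h))
    gx = max(1, min(grid, w))

    yb = np.linspace(0, h, gy + 1).astype(np.int64)
    xb = np.linspace(0, w, gx + 1).astype(np.int64)
    luts = np.empty((gy, gx, _NBINS), dtype=np.uint8)
    for ty in range(gy):
        for tx in range(gx):
            luts[ty, tx] = _tile_lut(img[yb[ty] : yb[ty + 1], xb[tx] : xb[tx + 1]], clip_limit)

    iy0, iy1, wy = _axis_coords(h, gy)
    ix0, ix1, wx = _axis_coords(w, gx)
    wy = wy[:, None]
    wx = wx[None, :]

    v00 = luts[iy0[:, None], ix0[None, :], img].astype(np.float64)
    v01 = luts[iy0[:, None], ix1[None, :], img].astype(np.float64)
    v10 = luts[iy1[:, None], ix0[None, :], img].astype(np.float64)
    v11 = luts[iy1[:, None], ix1[None, :], img].astype(np.float64)
    out = (1 - wy) * ((1 - wx) * v00 + wx * v01) + wy * ((1 - wx) * v10 + wx * v11)
    return np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)
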