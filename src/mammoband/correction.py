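"""Intensity-ramp flattening and contrast equalization around the defect.

The band defect is flanked by a smooth intensity ramp: brightness rises
toward the core on one side and falls on the other, decaying with
distance.  The flanks are covered with curvilinear quadrilateral tiles
(nominally 100x100 px) that follow the core's edge; within each tile the
per-column mean intensity is compared against a straight baseline drawn
from the minimum column mean on the illuminated side to the maximum
column mean on the darkened side, and the difference is subtracted from
every pixel of the column.  After flattening, the low-contrast side of
the image is equalized with CLAHE whose clip limit is set adaptively from
the two sides' intensity standard deviations:

    clip_limit = 1.11 - 0.023 * (stdB - stdA)

floored at 0.1 so the result is always a valid (positive) clip limit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .clahe import clahe
from .detection import BreastMask, DefectCore
from .image_io import GrayImage, as_gray_image

__all__ = [
    "FlankRegion",
    "ColumnProfile",
    "ContrastStats",
    "tile_flanks",
    "paired_region",
    "column_baseline",
    "flatten_ramp",
    "flatten_all_tiles",
    "brighter_flank",
    "side_stats",
    "adaptive_clip_limit",
    "equalize_low_contrast_side",
]

CLIP_LIMIT_FLOOR = 0.1


@dataclass
class FlankRegion:
    """A curvilinear quadrilateral tile on one flank of the core.

    ``cols`` maps each covered row to its absolute half-open column
    interval; the interval abuts the core (or the previous tile layer)
    and is clipped to the breast mask, so its width and vertical extent
    may fall short of the nominal tile size near the contour.  Columns
    within the region are addressed by *offset*: distance from the core
    edge, offset 0 being the column adjacent to the core.
    """

    side: str  # 'left' or 'right'
    rows: tuple[int, int]
    offsets: tuple[int, int]
    cols: dict[int, tuple[int, int]] = field(default_factory=dict)
    row_layer: int = 0
    col_layer: int = 0
    core_edge: dict[int, int] = field(default_factory=dict)

    @property
    def n_offsets(self) -> int:
        return self.offsets[1] - self.offsets[0]

    def column_pixels(self, offset: int) -> tuple[np.ndarray, np.ndarray]:
        """(rows, cols) of pixels at the given offset from the core edge."""
        rr, cc = [], []
        for r, (lo, hi) in self.cols.items():
            e = self.core_edge[r]
            c = e - 1 - offset if self.side == "left" else e + offset
            if lo <= c < hi:
                rr.append(r)
                cc.append(c)
        return np.asarray(rr, dtype=int), np.asarray(cc, dtype=int)

    def rasterize(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        for r, (lo, hi) in self.cols.items():
            out[r, lo:hi] = True
        return out


@dataclass
class ColumnProfile:
    """Per-column means and straight-line baseline for one region.

    ``offsets`` are the region column offsets that actually contain
    pixels; ``x`` their representative absolute column positions (mean
    over rows, so curvilinear regions get a consistent axis); ``means``
    the observed column means and ``baseline`` the affine baseline values
    at the same positions.
    """

    offsets: np.ndarray
    x: np.ndarray
    means: np.ndarray
    baseline: np.ndarray


@dataclass
class ContrastStats:
    """Histogram mode and standard deviation of the two sides.

    Side A is the high-contrast ("uncorrupted") side — the one with the
    larger standard deviation; side B the low-contrast side.  ``side_a``
    and ``side_b`` record which physical side (left/right of the core)
    each label refers to.
    """

    modeA: int
    modeB: int
    stdA: float
    stdB: float
    side_a: str
    side_b: str


def tile_flanks(
    core: DefectCore,
    mask: BreastMask,
    tile: int = 100,
    extent_layers: int = 4,
) -> list[FlankRegion]:
    """Cover both flanks of the core with curvilinear tiles.

    Tiles proceed outward from the core edge in ``tile``-column layers
    (up to ``extent_layers`` per side) and downward in ``tile``-row
    layers, each clipped to the breast mask.  Tiles are pairwise disjoint
    and their union covers the flank band up to the requested extent.
    """
    if core.is_empty or not core.connected:
        raise ValueError("tile_flanks requires a connected, non-empty core")
    top, bottom = core.row_span()
    regions: list[FlankRegion] = []
    n_row_layers = -(-(bottom - top) // tile)
    for side in ("left", "right"):
        for rl in range(n_row_layers):
            r0 = top + rl * tile
            r1 = min(top + (rl + 1) * tile, bottom)
            for cl in range(extent_layers):
                d0, d1 = cl * tile, (cl + 1) * tile
                cols: dict[int, tuple[int, int]] = {}
                edges: dict[int, int] = {}
                for r in range(r0, r1):
                    iv = core.intervals.get(r)
                    run = mask.row_run(r)
                    if iv is None or run is None:
                        continue
                    if side == "left":
                        e = iv[0]
                        lo, hi = e - d1, e - d0
                    else:
                        e = iv[1]
                        lo, hi = e + d0, e + d1
                    lo = max(lo, run[0])
                    hi = min(hi, run[1])
                    if side == "left":
                        hi = min(hi, iv[0])
                    else:
                        lo = max(lo, iv[1])
                    if hi > lo:
                        cols[r] = (lo, hi)
                        edges[r] = e
                if cols:
                    rows_present = sorted(cols)
                    regions.append(
                        FlankRegion(
                            side=side,
                            rows=(rows_present[0], rows_present[-1] + 1),
                            offsets=(d0, d1),
                            cols=cols,
                            row_layer=rl,
                            col_layer=cl,
                            core_edge=edges,
                        )
                    )
    return regions


def paired_region(region: FlankRegion, regions: list[FlankRegion]) -> FlankRegion | None:
    """The tile across the core at the same row and column layer."""
    other = "right" if region.side == "left" else "left"
    for r in regions:
        if r.side == other and r.row_layer == region.row_layer and r.col_layer == region.col_layer:
            return r
    return None


def _region_profile(img: np.ndarray, region: FlankRegion) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    offsets, xs, means = [], [], []
    for d in range(*region.offsets):
        rr, cc = region.column_pixels(d)
        if rr.size == 0:
            continue
        offsets.append(d)
        xs.append(float(cc.mean()))
        means.append(float(img[rr, cc].mean()))
    return (
        np.asarray(offsets, dtype=int),
        np.asarray(xs, dtype=np.float64),
        np.asarray(means, dtype=np.float64),
    )


def column_baseline(
    img: GrayImage,
    region: FlankRegion,
    bright_side: str,
    paired: FlankRegion | None = None,
) -> ColumnProfile:
    """Column means of a flank tile and their straight-line baseline.

    The baseline is the line through the *minimum* column mean on the
    illuminated (bright) side and the *maximum* column mean on the
    darkened side; when the region lies wholly on one side, the missing
    anchor comes from the paired tile across the core.  Without a paired
    tile the anchors fall back to the region's own extreme column means,
    which leaves affine and constant regions unchanged.
    """
    if bright_side not in ("left", "right"):
        raise ValueError(f"invalid bright_side {bright_side!r}")
    img = as_gray_image(img).astype(np.float64)
    offsets, xs, means = _region_profile(img, region)
    if offsets.size == 0:
        raise ValueError("empty flank region")

    if paired is not None and paired.side != region.side:
        p_off, p_xs, p_means = _region_profile(img, paired)
    else:
        p_off = np.empty(0, dtype=int)
        p_xs = p_means = np.empty(0)

    if region.side == bright_side:
        b_xs, b_means = xs, means
        d_xs, d_means = p_xs, p_means
    else:
        b_xs, b_means = p_xs, p_means
        d_xs, d_means = xs, means

    if b_means.size == 0 or d_means.size == 0:
        # Single-sided fallback: line through the region's own extremes.
        i_min = int(np.argmin(means))
        i_max = int(np.argmax(means))
        xb, yb = xs[i_min], means[i_min]
        xd, yd = xs[i_max], means[i_max]
    else:
        i_b = int(np.argmin(b_means))
        i_d = int(np.argmax(d_means))
        xb, yb = b_xs[i_b], b_means[i_b]
        xd, yd = d_xs[i_d], d_means[i_d]

    if xd == xb:
        baseline = np.full_like(means, (yb + yd) / 2.0)
    else:
        slope = (yd - yb) / (xd - xb)
        baseline = yb + slope * (xs - xb)
    return ColumnProfile(offsets=offsets, x=xs, means=means, baseline=baseline)


def flatten_ramp(img: GrayImage, region: FlankRegion, profile: ColumnProfile) -> GrayImage:
    """Subtract (column mean - baseline) from every pixel of each column.

    Pixels outside the region are untouched; results are clipped to
    [0, 255], so post-correction column means equal the baseline within
    rounding wherever no clipping occurred.
    """
    img = as_gray_image(img)
    out = img.astype(np.float64)
    for d, m, b in zip(profile.offsets, profile.means, profile.baseline):
        rr, cc = region.column_pixels(int(d))
        if rr.size:
            out[rr, cc] -= m - b
    return np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)


def brighter_flank(img: GrayImage, core: DefectCore, mask: BreastMask, tile: int = 100) -> str:
    """Decide which flank is illuminated: the side whose first tile
    adjacent to the core has the larger mean intensity."""
    img = as_gray_image(img)
    regions = tile_flanks(core, mask, tile=tile, extent_layers=1)
    sums = {"left": [0.0, 0], "right": [0.0, 0]}
    for reg in regions:
        sel = reg.rasterize(img.shape)
        n = int(sel.sum())
        if n:
            sums[reg.side][0] += float(img[sel].sum())
            sums[reg.side][1] += n
    means = {s: (v[0] / v[1] if v[1] else -np.inf) for s, v in sums.items()}
    return "left" if means["left"] >= means["right"] else "right"


def flatten_all_tiles(
    img: GrayImage,
    core: DefectCore,
    mask: BreastMask,
    tile: int = 100,
    extent_layers: int = 4,
    bright_side: str | None = None,
) -> GrayImage:
    """Flatten the intensity ramp over every flank tile (both sides)."""
    if bright_side is None:
        bright_side = brighter_flank(img, core, mask, tile=tile)
    regions = tile_flanks(core, mask, tile=tile, extent_layers=extent_layers)
    out = as_gray_image(img)
    for reg in regions:
        pair = paired_region(reg, regions)
        profile = column_baseline(out, reg, bright_side, paired=pair)
        out = flatten_ramp(out, reg, profile)
    return out


def _mode(values: np.ndarray) -> int:
    counts = np.bincount(values, minlength=256)
    return int(np.argmax(counts))  # ties -> smallest intensity


def side_stats(img: GrayImage, mask: BreastMask, core: DefectCore) -> ContrastStats:
    """Histogram mode and population std of the two sides of the defect.

    Pixels are partitioned by the core's column span; only in-mask,
    non-core pixels enter the statistics.  The side with the larger std
    is labeled A (high contrast), the other B.
    """
    img = as_gray_image(img)
    if core.is_empty or not core.connected:
        raise ValueError("side_stats requires a connected, non-empty core")
    lo, hi = core.col_span()
    cols = np.arange(img.shape[1])
    core_mask = core.rasterize(img.shape)
    left_sel = mask.mask & ~core_mask & (cols[None, :] < lo)
    right_sel = mask.mask & ~core_mask & (cols[None, :] >= hi)
    if not left_sel.any() or not right_sel.any():
        raise ValueError("a side of the defect has no in-mask pixels")
    lv = img[left_sel]
    rv = img[right_sel]
    std_l = float(np.std(lv))
    std_r = float(np.std(rv))
    if std_l >= std_r:
        return ContrastStats(
            modeA=_mode(lv), modeB=_mode(rv), stdA=std_l, stdB=std_r, side_a="left", side_b="right"
        )
    return ContrastStats(
        modeA=_mode(rv), modeB=_mode(lv), stdA=std_r, stdB=std_l, side_a="right", side_b="left"
    )


def adaptive_clip_limit(stats: ContrastStats, floor: float = CLIP_LIMIT_FLOOR) -> float:
    """Adaptive CLAHE clip limit from the two sides' standard deviations.

    ``clip_limit = 1.11 - 0.023 * (stdB - stdA)``, floored at ``floor``
    because CLAHE needs a positive clip limit and the regression can go
    non-positive for large contrast gaps.
    """
    return max(1.11 - 0.023 * (stats.stdB - stats.stdA), floor)


def equalize_low_contrast_side(
    img: GrayImage,
    mask: BreastMask,
    core: DefectCore,
    clip_limit: float,
    grid: int = 8,
    side: str | None = None,
    feather: int = 20,
) -> GrayImage:
    """Apply CLAHE to the low-contrast side only, feathered at the seam.

    ``side`` names the physical side ('left'/'right') to equalize; when
    omitted it is the smaller-std side from :func:`side_stats`.  CLAHE
    runs on the bounding box of that side's in-mask pixels (background
    filled with the side median so it does not skew tile histograms); the
    result is blended back with a linear feather over ``feather`` columns
    at the core boundary.  The high-contrast side is bit-identical to the
    input.
    """
    img = as_gray_image(img)
    if side is None:
        side = side_stats(img, mask, core).side_b
    if side not in ("left", "right"):
        raise ValueError(f"invalid side {side!r}")
    lo, hi = core.col_span()
    cols = np.arange(img.shape[1])
    core_mask = core.rasterize(img.shape)
    if side == "left":
        sel = mask.mask & ~core_mask & (cols[None, :] < lo)
    else:
        sel = mask.mask & ~core_mask & (cols[None, :] >= hi)
    if sel.sum() <= 1:
        warnings.warn("degenerate (<=1 px) low-contrast side; image returned unchanged")
        return img.copy()
    rows_any = np.flatnonzero(sel.any(axis=1))
    cols_any = np.flatnonzero(sel.any(axis=0))
    r0, r1 = rows_any[0], rows_any[-1] + 1
    c0, c1 = cols_any[0], cols_any[-1] + 1
    sub = img[r0:r1, c0:c1]
    sub_sel = sel[r0:r1, c0:c1]
    fill = int(np.median(sub[sub_sel]))
    eq = clahe(np.where(sub_sel, sub, fill).astype(np.uint8), clip_limit, grid=grid)

    # Feather: weight 0 at the core-adjacent boundary, 1 past `feather` cols.
    sub_cols = np.arange(c0, c1)
    if side == "left":
        dist = (lo - 1) - sub_cols
    else:
        dist = sub_cols - hi
    alpha = np.clip(dist / max(feather, 1), 0.0, 1.0)[None, :]
    blended = (1 - alpha) * sub.astype(np.float64) + alpha * eq.astype(np.float64)
    blended = np.clip(np.floor(blended + 0.5), 0, 255).astype(np.uint8)
    out = img.copy()
    out[r0:r1, c0:c1] = np.where(sub_sel, blended, out[r0:r1, c0:c1])
    return out
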