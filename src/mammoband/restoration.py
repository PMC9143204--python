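"""Restoring the defect core: interpolation + background inpainting + fusion.

Inside the core the original signal is gone, so two complementary
restorations are fused.  Per-row polynomial interpolation (degree 1 by
default; higher degrees give artifacts) carries the bright streaks —
vessels and fibrous tissue — across the band but leaves horizontal
banding in the background.  A background restorer (any hole-filling
procedure honouring a simple contract; the default is classical
biharmonic inpainting) reconstructs a plausible smooth background but
blurs the streaks.  A streak mask is extracted from the interpolated
image by boosting contrast with CLAHE (clip limit 20) and binarizing at
the global threshold 170 — intensities of 171-255 are the informative
part — and the composite takes interpolated values where the mask is set
and background values elsewhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .clahe import clahe
from .correction import (
    adaptive_clip_limit,
    equalize_low_contrast_side,
    flatten_all_tiles,
    side_stats,
    ContrastStats,
)
from .detection import (
    BreastMask,
    DefectCore,
    connect_core_segments,
    detect_defect_core,
    find_breast_contour,
)
from .image_io import GrayImage, as_gray_image

logger = logging.getLogger(__name__)

__all__ = [
    "StreakMask",
    "RestorationBundle",
    "PipelineConfig",
    "ContractViolationError",
    "BiharmonicRestorer",
    "CoarseFineRestorer",
    "interpolate_core",
    "restore_background",
    "streak_mask",
    "overlay",
    "restore_pipeline",
]


class ContractViolationError(ValueError):
    """A pluggable component broke its interface contract."""


@dataclass
class StreakMask:
    """Binary raster of significant bright lines in the core window."""

    mask: np.ndarray
    window_rows: tuple[int, int] = (0, 0)
    window_cols: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class PipelineConfig:
    """All tunables of the end-to-end pipeline, defaulted to the
    algorithm's published operating point (thresholds 220/170, tile 100,
    grid 8, streak-mask clip limit 20, first-degree interpolation)."""

    low_thresh: int = 5
    hi_thresh: int = 220
    tile: int = 100
    extent_layers: int = 4
    grid: int = 8
    clip_floor: float = 0.1
    interp_degree: int = 1
    flank_k: int = 3
    mask_clip: float = 20.0
    mask_threshold: int = 170
    mask_margin: int = 50
    feather: int = 20
    restorer: str = "classical"  # or "coarse-fine"


@dataclass
class RestorationBundle:
    """All rasters produced by the pipeline, congruent with the input."""

    interpolated: GrayImage
    background: GrayImage
    mask: StreakMask
    composite: GrayImage
    core: DefectCore | None = None
    breast: BreastMask | None = None
    stats: ContrastStats | None = None
    clip_limit: float | None = None


class BiharmonicRestorer:
    """Default background restorer: classical biharmonic inpainting."""

    def __call__(self, img: GrayImage, hole: np.ndarray) -> GrayImage:
        from skimage.restoration import inpaint_biharmonic

        img = as_gray_image(img)
        hole = np.asarray(hole, dtype=bool)
        if not hole.any():
            return img.copy()
        out = inpaint_biharmonic(img, hole)
        return np.clip(np.floor(out * 255.0 + 0.5), 0, 255).astype(np.uint8)


class CoarseFineRestorer:
    """Coarse-fine background restorer around any hole filler.

    Fills the hole coarsely at 256x256, refines at 512x512 starting from
    the upsampled coarse fill, and sharpens the upsampled result inside
    the hole with a contextual residual (the difference between the image
    and its down/up-sampled copy) transferred from the nearest out-of-hole
    pixel — a nearest-neighbour stand-in for learned attention transfer.
    """

    def __init__(self, base=None, coarse_size: int | None = None, refine_size: int | None = None):
        self.base = base if base is not None else BiharmonicRestorer()
        # Default working sizes scale with the image: 1/16 and 1/8 of the
        # short dimension, which on a full-size mammogram (~4000 px)
        # reproduces the conventional 256/512 coarse-fine resolutions.
        self.coarse_size = coarse_size
        self.refine_size = refine_size

    def _sizes(self, shape: tuple[int, int]) -> tuple[int, int]:
        short = min(shape)
        coarse = self.coarse_size if self.coarse_size is not None else max(16, short // 16)
        refine = self.refine_size if self.refine_size is not None else max(32, short // 8)
        return coarse, refine

    @staticmethod
    def _resize(img: np.ndarray, shape: tuple[int, int], order: int) -> np.ndarray:
        from skimage.transform import resize

        return resize(img.astype(np.float64), shape, order=order, mode="edge",
                      anti_aliasing=order > 0, preserve_range=True)

    def _fill_at(self, img: np.ndarray, hole: np.ndarray, size: int) -> np.ndarray:
        h, w = img.shape
        scale = min(size / h, size / w, 1.0)
        shape = (max(1, round(h * scale)), max(1, round(w * scale)))
        small = np.clip(np.round(self._resize(img, shape, 1)), 0, 255).astype(np.uint8)
        small_hole = self._resize(hole.astype(np.float64), shape, 0) > 0.5
        # Keep at least the scaled hole footprint one pixel wide.
        if hole.any() and not small_hole.any():
            cols = np.flatnonzero(hole.any(axis=0))
            c = min(int(round(cols.mean() * scale)), shape[1] - 1)
            small_hole[:, c] = True
        filled = self.base(small, small_hole)
        return self._resize(filled, img.shape, 1)

    def __call__(self, img: GrayImage, hole: np.ndarray) -> GrayImage:
        img = as_gray_image(img)
        hole = np.asarray(hole, dtype=bool)
        if not hole.any():
            return img.copy()
        coarse_size, refine_size = self._sizes(img.shape)
        coarse = self._fill_at(img.astype(np.float64), hole, coarse_size)
        init = np.where(hole, coarse, img.astype(np.float64))
        refined = self._fill_at(init, hole, refine_size)

        # Contextual residual: detail lost by a down/up-sample round trip,
        # computed on the hole-filled image so the hole itself cannot
        # bleed into the residual near its boundary.
        h, w = img.shape
        scale = min(refine_size / h, refine_size / w, 1.0)
        shape = (max(1, round(h * scale)), max(1, round(w * scale)))
        filled_full = np.where(hole, refined, img.astype(np.float64))
        smooth = self._resize(self._resize(filled_full, shape, 1), (h, w), 1)
        residual = filled_full - smooth
        # Transfer each hole pixel's residual from the nearest known pixel.
        _, (ir, ic) = ndimage.distance_transform_edt(hole, return_indices=True)
        transferred = residual[ir, ic]
        out = np.where(hole, refined + transferred, img.astype(np.float64))
        return np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)


def make_restorer(name: str):
    if name == "classical":
        return BiharmonicRestorer()
    if name == "coarse-fine":
        return CoarseFineRestorer()
    raise ValueError(f"unknown restorer {name!r}")


def interpolate_core(
    img: GrayImage, core: DefectCore, degree: int = 1, flank_k: int = 3
) -> GrayImage:
    """Fill each core row by polynomial interpolation across the band.

    For degree 1 the polynomial passes through two anchors, each the mean
    value (at the mean column position) of ``flank_k`` columns
    immediately left and right of the interval.  Degrees 2-3 fit a
    least-squares polynomial through the individual flank pixels.  An
    interval touching the image edge is extended as a constant from the
    available side.
    """
    if degree not in (1, 2, 3):
        raise ValueError("degree must be in {1, 2, 3}")
    if flank_k < 1:
        raise ValueError("flank_k must be >= 1")
    img = as_gray_image(img)
    out = img.astype(np.float64)
    h, w = img.shape
    for r, (lo, hi) in core.intervals.items():
        if hi <= lo:
            continue
        lcols = np.arange(max(lo - flank_k, 0), lo)
        rcols = np.arange(hi, min(hi + flank_k, w))
        xs = np.arange(lo, hi, dtype=np.float64)
        if lcols.size == 0 and rcols.size == 0:
            continue
        if lcols.size == 0:
            out[r, lo:hi] = float(img[r, rcols].mean())
            continue
        if rcols.size == 0:
            out[r, lo:hi] = float(img[r, lcols].mean())
            continue
        if degree == 1:
            xl, yl = float(lcols.mean()), float(img[r, lcols].mean())
            xr, yr = float(rcols.mean()), float(img[r, rcols].mean())
            vals = yl + (xs - xl) * (yr - yl) / (xr - xl)
        else:
            px = np.concatenate([lcols, rcols]).astype(np.float64)
            py = img[r, np.concatenate([lcols, rcols])].astype(np.float64)
            deg = min(degree, px.size - 1)
            coeffs = np.polyfit(px - lo, py, deg)
            vals = np.polyval(coeffs, xs - lo)
        out[r, lo:hi] = vals
    return np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)


def restore_background(img: GrayImage, core: DefectCore, restorer=None) -> GrayImage:
    """Replace core pixels with the background restorer's output.

    The restorer contract: given the image and a boolean hole mask,
    return a congruent uint8 image identical to the input outside the
    hole.  Violations raise :class:`ContractViolationError`.
    """
    img = as_gray_image(img)
    if restorer is None:
        restorer = BiharmonicRestorer()
    hole = core.rasterize(img.shape)
    out = restorer(img, hole)
    out = np.asarray(out)
    if out.shape != img.shape:
        raise ContractViolationError(
            f"restorer returned shape {out.shape}, expected {img.shape}"
        )
    out = as_gray_image(out)
    if np.any(out[~hole] != img[~hole]):
        raise ContractViolationError("restorer modified pixels outside the hole")
    return out


def streak_mask(
    interpolated: GrayImage,
    core: DefectCore,
    margin: int = 50,
    mask_clip: float = 20.0,
    threshold: int = 170,
    grid: int = 8,
) -> StreakMask:
    """Binarized bright-line mask over the core-plus-margin window.

    CLAHE with the given clip limit boosts contrast in the window of the
    interpolated image; pixels whose boosted intensity exceeds
    ``threshold`` (i.e. lies in [threshold+1, 255]) are the informative
    part, everything else is background.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    interpolated = as_gray_image(interpolated)
    h, w = interpolated.shape
    mask = np.zeros((h, w), dtype=bool)
    if core.is_empty:
        return StreakMask(mask=mask)
    top, bottom = core.row_span()
    lo, hi = core.col_span()
    c0 = max(lo - margin, 0)
    c1 = min(hi + margin, w)
    window = interpolated[top:bottom, c0:c1]
    if window.size == 0:
        return StreakMask(mask=mask, window_rows=(top, bottom), window_cols=(c0, c1))
    boosted = clahe(window, mask_clip, grid=grid)
    mask[top:bottom, c0:c1] = boosted > threshold
    return StreakMask(mask=mask, window_rows=(top, bottom), window_cols=(c0, c1))


def overlay(background: GrayImage, interpolated: GrayImage, mask: StreakMask | np.ndarray) -> GrayImage:
    """Composite: interpolated where the mask is set, background elsewhere."""
    background = as_gray_image(background)
    interpolated = as_gray_image(interpolated)
    m = mask.mask if isinstance(mask, StreakMask) else np.asarray(mask, dtype=bool)
    if background.shape != interpolated.shape or m.shape != background.shape:
        raise ValueError("overlay inputs must be congruent")
    return np.where(m, interpolated, background)


def _clip_core_to_mask(core: DefectCore, mask: BreastMask) -> DefectCore:
    intervals = {}
    for r, (lo, hi) in core.intervals.items():
        run = mask.row_run(r)
        if run is None:
            continue
        lo2, hi2 = max(lo, run[0]), min(hi, run[1])
        if hi2 > lo2:
            intervals[r] = (lo2, hi2)
    return DefectCore(intervals=intervals, connected=core.connected)


def _pseudo_core_at(mask: BreastMask) -> DefectCore:
    """Zero-width core at the breast's median column; used to partition
    the sides for contrast equalization when no defect is found."""
    centers = []
    rows = []
    for r in range(mask.shape[0]):
        run = mask.row_run(r)
        if run is not None:
            rows.append(r)
            centers.append((run[0] + run[1]) // 2)
    c = int(np.median(centers))
    return DefectCore(intervals={r: (c, c) for r in rows}, connected=True)


def restore_pipeline(img: GrayImage, config: PipelineConfig | None = None, restorer=None) -> RestorationBundle:
    """Run the full band-defect elimination pipeline.

    Stages: breast contour -> defect core -> segment connection -> flank
    ramp flattening -> adaptive contrast equalization -> core
    interpolation -> background restoration -> streak mask -> overlay.
    If no core is found the pipeline bypasses restoration and returns the
    contrast-equalized image with an empty mask.
    """
    if config is None:
        config = PipelineConfig()
    img = as_gray_image(img)
    if restorer is None:
        restorer = make_restorer(config.restorer)

    breast = find_breast_contour(img, low_thresh=config.low_thresh)
    logger.info("breast contour: %d in-mask pixels", int(breast.mask.sum()))
    core = detect_defect_core(img, breast, hi_thresh=config.hi_thresh)
    if core.is_empty:
        logger.info("no defect core found; bypassing restoration")
        pseudo = _pseudo_core_at(breast)
        stats = side_stats(img, breast, pseudo)
        clip = adaptive_clip_limit(stats, floor=config.clip_floor)
        equalized = equalize_low_contrast_side(
            img, breast, pseudo, clip, grid=config.grid, side=stats.side_b,
            feather=config.feather,
        )
        empty = StreakMask(mask=np.zeros(img.shape, dtype=bool))
        return RestorationBundle(
            interpolated=equalized, background=equalized, mask=empty,
            composite=equalized, core=core, breast=breast, stats=stats,
            clip_limit=clip,
        )

    core = connect_core_segments(core)
    core = _clip_core_to_mask(core, breast)
    logger.info("defect core: rows %s, columns %s", core.row_span(), core.col_span())

    flattened = flatten_all_tiles(
        img, core, breast, tile=config.tile, extent_layers=config.extent_layers
    )
    logger.info("flank ramp flattened over %d tile layers/side", config.extent_layers)

    stats = side_stats(flattened, breast, core)
    clip = adaptive_clip_limit(stats, floor=config.clip_floor)
    logger.info(
        "side stats: stdA=%.2f (%s) stdB=%.2f (%s) -> clip_limit=%.3f",
        stats.stdA, stats.side_a, stats.stdB, stats.side_b, clip,
    )
    equalized = equalize_low_contrast_side(
        flattened, breast, core, clip, grid=config.grid, side=stats.side_b,
        feather=config.feather,
    )

    interpolated = interpolate_core(
        equalized, core, degree=config.interp_degree, flank_k=config.flank_k
    )
    background = restore_background(equalized, core, restorer=restorer)
    smask = streak_mask(
        interpolated, core, margin=config.mask_margin, mask_clip=config.mask_clip,
        threshold=config.mask_threshold, grid=config.grid,
    )
    logger.info("streak mask: %d informative pixels", int(smask.mask.sum()))
    composite = overlay(background, interpolated, smask)
    return RestorationBundle(
        interpolated=interpolated, background=background, mask=smask,
        composite=composite, core=core, breast=breast, stats=stats,
        clip_limit=clip,
    )
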