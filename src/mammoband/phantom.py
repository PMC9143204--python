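"""Seeded synthetic mammogram-like phantoms with ground truth.

No clinical mammograms ship with this package, so every pipeline stage is
exercised on phantoms that emulate the morphology the algorithm assumes:
a breast-shaped bright region (half-ellipse flush with the left image
edge) on a black background, smooth tissue-like texture, bright
curvilinear streaks standing in for vessels and fibrous tissue, and an
injectable vertical band defect — intensity raised (optionally to full
saturation) inside the band, a smooth ramp decaying over the flanks, an
intensity drop on the opposite side, and an optional one-sided contrast
degradation.

Every phantom is a pure function of its spec: one ``numpy.random.
Generator`` seeded explicitly, no global random state, bit-identical
output for identical specs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .image_io import GrayImage, as_gray_image

__all__ = [
    "PhantomSpec",
    "DefectSpec",
    "PhantomTruth",
    "generate_phantom",
    "generate_phantom_with_truth",
    "inject_band_defect",
    "cut_strip",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the defect-free phantom.

    ``texture_scale`` is the correlation length (pixels) of the smooth
    tissue texture; ``noise_std`` its amplitude in intensity units.
    Streak brightness is drawn uniformly from ``streak_gain`` above the
    local background, within the 10-60 unit range typical of vessel and
    fibrous-tissue lines on an 8-bit mammogram.
    """

    height: int = 512
    width: int = 512
    seed: int = 0
    n_streaks: int = 5
    background_level: int = 120
    texture_scale: float = 8.0
    noise_std: float = 6.0
    streak_gain: tuple[float, float] = (30.0, 60.0)
    streak_halfwidth: int = 1
    #: fine fibrous strands forming the tissue texture (dimmer, denser
    #: than the prominent streaks); count scales the fibroglandular
    #: density typical of a mammogram.
    n_fibers: int = 35
    fiber_gain: tuple[float, float] = (10.0, 30.0)

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("phantom dimensions must be positive")
        if not 0 <= self.background_level <= 255:
            raise ValueError("background_level must be in [0, 255]")
        if self.n_streaks < 0:
            raise ValueError("n_streaks must be >= 0")


@dataclass
class DefectSpec:
    """Ground-truth description of an injected vertical band defect.

    ``gain_profile`` / ``loss_profile`` are the additive rise inside the
    band and the subtractive drop at the dark flank's inner edge; either
    a scalar or a per-row array.  The band brightens toward ``side`` and
    darkens on the other side; both flanks decay as a raised cosine over
    ``flank_width`` columns.  ``ramp_gain`` is the bright-flank shoulder
    amplitude (defaults to ``min(gain, 60)`` so a saturating band keeps a
    detectable edge).  ``contrast_factor`` rescales the dark side about
    its mean (1.0 = untouched); ``blur_sigma`` optionally blurs it.
    """

    center_col: int = 150
    width: int = 15
    side: str = "left-bright"
    gain_profile: object = 255.0
    loss_profile: object = 30.0
    contrast_factor: float = 1.0
    flank_width: int = 150
    ramp_gain: float | None = None
    blur_sigma: float = 0.0
    zero_band: bool = False

    def __post_init__(self) -> None:
        if self.width < 0:
            raise ValueError("band width must be >= 0")
        if self.side not in ("left-bright", "right-bright"):
            raise ValueError(f"invalid side {self.side!r}")
        if not 0 < self.contrast_factor <= 1:
            raise ValueError("contrast_factor must be in (0, 1]")

    @property
    def band(self) -> tuple[int, int]:
        """Half-open [left, right) column interval of the band."""
        lo = self.center_col - self.width // 2
        return lo, lo + self.width

    def to_json_dict(self) -> dict:
        d = asdict(self)
        for k in ("gain_profile", "loss_profile"):
            if isinstance(d[k], np.ndarray):
                d[k] = d[k].tolist()
        return d


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom."""

    breast_mask: np.ndarray
    streak_mask: np.ndarray
    background: GrayImage  # phantom without streaks


def _breast_mask(h: int, w: int) -> np.ndarray:
    # Half-ellipse flush with the left edge; area fraction pi/2*0.48*0.80
    # ~ 0.60 of the frame, inside the 30-70% contract.
    cy = (h - 1) / 2.0
    b = 0.48 * h
    a = 0.80 * w
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    return (cols / a) ** 2 + ((rows - cy) / b) ** 2 <= 1.0


def _texture_field(rng: np.random.Generator, h: int, w: int, scale: float, std: float) -> np.ndarray:
    # Value noise: coarse Gaussian grid upsampled with cubic interpolation.
    # The amplitude stays ~std for any scale, and scale -> inf degenerates
    # to a single grid point, i.e. a flat field.
    gh = max(1, int(round(h / max(scale, 1e-9))))
    gw = max(1, int(round(w / max(scale, 1e-9))))
    coarse = rng.standard_normal((gh, gw)) * std
    if (gh, gw) == (h, w):
        return coarse
    return ndimage.zoom(coarse, (h / gh, w / gw), order=3, grid_mode=True, mode="nearest")


def _draw_streaks(
    rng: np.random.Generator,
    mask: np.ndarray,
    count: int,
    gain_range: tuple[float, float],
    halfwidth: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Additive streak field and its boolean support raster."""
    h, w = mask.shape
    add = np.zeros((h, w), dtype=np.float64)
    support = np.zeros((h, w), dtype=bool)
    rows_in = np.flatnonzero(mask.any(axis=1))
    if rows_in.size == 0:
        return add, support
    for _ in range(count):
        gain = rng.uniform(*gain_range)
        # Random chord through the breast with a sinusoidal bow normal to
        # it: vessels and fibrous strands run in every orientation, so
        # streaks cross the (vertical) defect band transversally as often
        # as not.
        p0 = np.array([rng.choice(rows_in), rng.uniform(0.0, 0.7 * w)])
        p1 = np.array([rng.choice(rows_in), rng.uniform(0.0, 0.7 * w)])
        if np.linalg.norm(p1 - p0) < 0.3 * min(h, w):
            p1 = p0 + (p1 - p0 + 1e-6) / (np.linalg.norm(p1 - p0) + 1e-6) * 0.3 * min(h, w)
        chord = p1 - p0
        normal = np.array([-chord[1], chord[0]]) / (np.linalg.norm(chord) + 1e-9)
        amp = rng.uniform(0.02, 0.10) * min(h, w)
        phase = rng.uniform(0, 2 * np.pi)
        n = max(2, int(2 * np.linalg.norm(chord)) + 2)
        t = np.linspace(0.0, 1.0, n)
        pts = p0[None, :] + t[:, None] * chord[None, :]
        pts = pts + (amp * np.sin(np.pi * t + phase))[:, None] * normal[None, :]
        rr = np.clip(np.round(pts[:, 0]).astype(int), 0, h - 1)
        cc = np.clip(np.round(pts[:, 1]).astype(int), 0, w - 1)
        line = np.zeros((h, w), dtype=bool)
        line[rr, cc] = True
        if halfwidth > 0:
            line = ndimage.binary_dilation(line, iterations=halfwidth)
        line &= mask
        add = np.maximum(add, line * gain)
        support |= line
    # Soften streak edges slightly without flattening the ridge; the
    # blur must not bleed outside the breast (background stays black).
    add = ndimage.gaussian_filter(add, sigma=0.6)
    add[~mask] = 0.0
    return add, support


def generate_phantom_with_truth(spec: PhantomSpec) -> tuple[GrayImage, PhantomTruth]:
    """Generate a phantom together with its ground truth rasters."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    mask = _breast_mask(h, w)
    tissue = spec.background_level + _texture_field(rng, h, w, spec.texture_scale, spec.noise_std)
    fibers, _ = _draw_streaks(rng, mask, spec.n_fibers, spec.fiber_gain, 0)
    background = np.where(mask, tissue + fibers, 0.0)
    streaks, support = _draw_streaks(
        rng, mask, spec.n_streaks, spec.streak_gain, spec.streak_halfwidth
    )
    img = np.clip(np.floor(background + streaks + 0.5), 0, 255).astype(np.uint8)
    bg_img = np.clip(np.floor(background + 0.5), 0, 255).astype(np.uint8)
    return img, PhantomTruth(breast_mask=mask, streak_mask=support, background=bg_img)


def generate_phantom(spec: PhantomSpec) -> GrayImage:
    """Generate a seeded synthetic mammogram-like image."""
    img, _ = generate_phantom_with_truth(spec)
    return img


def _as_row_profile(value: object, h: int) -> np.ndarray:
    arr = np.asarray(value, dtype=np.float64)
    if arr.ndim == 0:
        return np.full(h, float(arr))
    if arr.shape != (h,):
        raise ValueError(f"per-row profile must have length {h}")
    return arr


def _raised_cosine(dist: np.ndarray, flank: int) -> np.ndarray:
    """1 at the band edge, 0 beyond ``flank`` columns, smooth in between."""
    if flank <= 0:
        return np.zeros_like(dist, dtype=np.float64)
    r = np.clip(dist / flank, 0.0, 1.0)
    return 0.5 * (1.0 + np.cos(np.pi * r)) * (dist < flank)


def inject_band_defect(img: GrayImage, d: DefectSpec) -> tuple[GrayImage, DefectSpec]:
    """Add a vertical band defect to a phantom; returns (image, truth).

    Inside the band intensity rises by ``gain_profile`` (clipped at 255,
    or forced to 0 with ``zero_band``); the bright flank carries a
    raised-cosine ramp of amplitude ``ramp_gain``; the dark flank is
    lowered by ``loss_profile`` times the same ramp; the dark side is
    contrast-reduced by ``contrast_factor`` and optionally blurred.  Only
    in-breast (nonzero) pixels are modified, so the black background and
    the breast contour stay intact.
    """
    img = as_gray_image(img)
    h, w = img.shape
    lo, hi = d.band
    if d.width > 0 and not (0 <= lo and hi <= w):
        raise ValueError(f"band [{lo}, {hi}) outside image of width {w}")
    gain = _as_row_profile(d.gain_profile, h)
    loss = _as_row_profile(d.loss_profile, h)
    ramp_gain = d.ramp_gain if d.ramp_gain is not None else min(float(np.mean(gain)), 60.0)

    out = img.astype(np.float64)
    in_breast = img > 0
    cols = np.arange(w)
    bright_left = d.side == "left-bright"
    if bright_left:
        bright_cols = cols < lo
        dark_cols = cols >= hi
        bright_dist = lo - 1 - cols
        dark_dist = cols - hi
    else:
        bright_cols = cols >= hi
        dark_cols = cols < lo
        bright_dist = cols - hi
        dark_dist = lo - 1 - cols

    # One-sided contrast degradation on the dark side, about its in-breast mean.
    if d.contrast_factor < 1.0 or d.blur_sigma > 0:
        side_sel = in_breast & dark_cols[None, :]
        if side_sel.any():
            side_vals = out[side_sel]
            m = side_vals.mean()
            out[side_sel] = m + d.contrast_factor * (side_vals - m)
            if d.blur_sigma > 0:
                blurred = ndimage.gaussian_filter(out, sigma=d.blur_sigma)
                out[side_sel] = blurred[side_sel]

    if d.width > 0:
        bright_ramp = np.zeros(w, dtype=np.float64)
        bright_ramp[bright_cols] = ramp_gain * _raised_cosine(bright_dist[bright_cols], d.flank_width)
        dark_ramp = np.zeros(w, dtype=np.float64)
        dark_ramp[dark_cols] = _raised_cosine(dark_dist[dark_cols], d.flank_width)
        band = np.zeros(w, dtype=bool)
        band[lo:hi] = True
        field = np.where(band[None, :], gain[:, None], bright_ramp[None, :])
        field = field - loss[:, None] * dark_ramp[None, :]
        out = np.where(in_breast, out + field, out)
        if d.zero_band:
            out = np.where(in_breast & band[None, :], 0.0, out)
    result = np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)
    return result, d


def cut_strip(img: GrayImage, col: int, width: int) -> tuple[GrayImage, DefectSpec]:
    """Zero a vertical strip of ``width`` columns starting at ``col``.

    Emulates the cut-strip evaluation experiment: the excised columns are
    a known, fully destroyed "defect core" with pristine surroundings.
    """
    img = as_gray_image(img)
    h, w = img.shape
    if width < 0:
        raise ValueError("width must be >= 0")
    if width > 0 and not (0 <= col and col + width <= w):
        raise ValueError(f"strip [{col}, {col + width}) outside image of width {w}")
    out = img.copy()
    out[:, col : col + width] = 0
    truth = DefectSpec(
        center_col=col + width // 2,
        width=width,
        gain_profile=0.0,
        loss_profile=0.0,
        flank_width=0,
        ramp_gain=0.0,
        zero_band=True,
    )
    return out, truth
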