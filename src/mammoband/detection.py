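"""Breast-contour and defect-core detection.

The defect core is the part of the band where information is destroyed
outright: pixels brighter than a hard threshold (default 220, strict
inequality) or exactly zero.  Because the band's brightness varies along
its length, the core may be absent in some rows; those gaps are closed by
linearly interpolating the interval bounds between the nearest detected
rows, yielding a single vertically contiguous band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image_io import GrayImage, as_gray_image

__all__ = [
    "BreastMask",
    "DefectCore",
    "find_breast_contour",
    "detect_defect_core",
    "connect_core_segments",
]


@dataclass
class BreastMask:
    """Boolean raster marking the breast region (one run per row)."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def row_run(self, row: int) -> tuple[int, int] | None:
        """Half-open [left, right) column run of the breast in *row*."""
        cols = np.flatnonzero(self.mask[row])
        if cols.size == 0:
            return None
        return int(cols[0]), int(cols[-1]) + 1


@dataclass
class DefectCore:
    """Per-row half-open column intervals of the defect core.

    ``intervals`` maps row index to ``(left, right)`` with the usual
    0-based half-open convention.  ``connected`` is set once gap rows have
    been filled by :func:`connect_core_segments`.
    """

    intervals: dict[int, tuple[int, int]] = field(default_factory=dict)
    connected: bool = False

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def is_empty(self) -> bool:
        return not self.intervals

    def row_span(self) -> tuple[int, int]:
        """Half-open [top, bottom) row range covered by intervals."""
        if self.is_empty:
            raise ValueError("empty defect core")
        rows = sorted(self.intervals)
        return rows[0], rows[-1] + 1

    def col_span(self) -> tuple[int, int]:
        """Half-open [left, right) hull of all intervals."""
        if self.is_empty:
            raise ValueError("empty defect core")
        lefts, rights = zip(*self.intervals.values())
        return min(lefts), max(rights)

    def rasterize(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean raster of the core on an image of the given shape."""
        out = np.zeros(shape, dtype=bool)
        for r, (lo, hi) in self.intervals.items():
            out[r, lo:hi] = True
        return out

    def median_center(self) -> float:
        """Median of per-row interval centers (robust band axis)."""
        if self.is_empty:
            raise ValueError("empty defect core")
        centers = [(lo + hi - 1) / 2.0 for lo, hi in self.intervals.values()]
        return float(np.median(centers))

    def median_width(self) -> float:
        """Median of per-row interval widths (robust band width)."""
        if self.is_empty:
            raise ValueError("empty defect core")
        return float(np.median([hi - lo for lo, hi in self.intervals.values()]))


def find_breast_contour(img: GrayImage, low_thresh: int = 5, side: str = "auto") -> BreastMask:
    """Locate the breast by scanning each row inward from the borders.

    Moving from the left and right image borders toward the center, a
    pixel enters the mask once its intensity exceeds ``low_thresh``; the
    row's run is everything between the first such pixel from either
    border.  Rows with no qualifying pixel get an empty run.  ``side`` is
    accepted for interface symmetry ({"left", "right", "auto"}) — the
    two-border scan yields the same run regardless of which edge the
    breast is flush with.
    """
    if side not in ("left", "right", "auto"):
        raise ValueError(f"invalid side {side!r}")
    if not 0 <= low_thresh <= 255:
        raise ValueError("low_thresh must be in [0, 255]")
    img = as_gray_image(img)
    h, w = img.shape
    bright = img > low_thresh
    has = bright.any(axis=1)
    left = np.argmax(bright, axis=1)
    right = w - np.argmax(bright[:, ::-1], axis=1)
    cols = np.arange(w)
    mask = has[:, None] & (cols[None, :] >= left[:, None]) & (cols[None, :] < right[:, None])
    return BreastMask(mask)


def _row_runs(qual_row: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open intervals."""
    padded = np.concatenate(([False], qual_row, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]


def detect_defect_core(img: GrayImage, mask: BreastMask, hi_thresh: int = 220) -> DefectCore:
    """Find per-row core intervals: in-mask pixels with intensity
    strictly above ``hi_thresh`` or exactly zero.

    When a row holds several disjoint qualifying runs (stray bright
    specks), the run whose center is nearest the median core column over
    all rows is kept — the defect is a single vertical structure.
    """
    img = as_gray_image(img)
    if mask.shape != img.shape:
        raise ValueError("mask not congruent with image")
    qual = mask.mask & ((img > hi_thresh) | (img == 0))
    runs_by_row: dict[int, list[tuple[int, int]]] = {}
    for r in np.flatnonzero(qual.any(axis=1)):
        runs_by_row[int(r)] = _row_runs(qual[r])
    if not runs_by_row:
        return DefectCore()

    # First pass: the longest run per row votes for the band axis.
    longest_centers = []
    for runs in runs_by_row.values():
        lo, hi = max(runs, key=lambda iv: (iv[1] - iv[0], -iv[0]))
        longest_centers.append((lo + hi - 1) / 2.0)
    axis = float(np.median(longest_centers))

    intervals: dict[int, tuple[int, int]] = {}
    for r, runs in runs_by_row.items():
        best = min(runs, key=lambda iv: (abs((iv[0] + iv[1] - 1) / 2.0 - axis), iv[0]))
        intervals[r] = best
    return DefectCore(intervals=intervals, connected=False)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def connect_core_segments(core: DefectCore) -> DefectCore:
    """Fill gap rows between the topmost and bottommost core intervals.

    Missing rows get bounds linearly interpolated (in row index) between
    the nearest bounded rows above and below, rounded half-up.  The
    operation is idempotent and never shrinks an existing interval.
    """
    if core.is_empty:
        raise ValueError("cannot connect an empty defect core")
    rows = sorted(core.intervals)
    intervals = dict(core.intervals)
    for ra, rb in zip(rows[:-1], rows[1:]):
        if rb - ra == 1:
            continue
        la, ha = core.intervals[ra]
        lb, hb = core.intervals[rb]
        for r in range(ra + 1, rb):
            t = (r - ra) / (rb - ra)
            lo = _round_half_up(la + t * (lb - la))
            hi = _round_half_up(ha + t * (hb - ha))
            if hi <= lo:
                hi = lo + 1
            intervals[r] = (lo, hi)
    return DefectCore(intervals=intervals, connected=True)
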