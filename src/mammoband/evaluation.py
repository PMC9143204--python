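"""Restoration quality metrics and feature-drift statistics.

Three evaluation tools quantify how faithfully the pipeline restores an
image and how little it perturbs downstream analysis:

* a full-reference metric suite (built-in SSIM and GMSD; further metrics
  and the no-reference BRISQUE/NIQE scorers plug in behind a uniform
  contract),
* the cut-strip experiment — excise a thin pristine strip, restore it by
  interpolation alone, background inpainting alone, and the fused
  overlay, and score each against the uncut original,
* radiomics feature drift — the 18 first-order descriptors per image
  group, compared across groups with one-way ANOVA and the Tukey HSD
  studentized-range test, summarised as the percentage of features that
  differ significantly from the originals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats as sstats

from .detection import BreastMask, DefectCore
from .image_io import GrayImage, as_gray_image
from .phantom import cut_strip
from .restoration import (
    PipelineConfig,
    interpolate_core,
    overlay,
    restore_background,
    streak_mask,
)

__all__ = [
    "MetricPlugin",
    "MetricReport",
    "BUILTIN_METRICS",
    "compute_ssim",
    "compute_gmsd",
    "metric_report",
    "strip_experiment",
    "FIRST_ORDER_NAMES",
    "first_order_features",
    "FeatureTable",
    "build_feature_table",
    "AnovaResult",
    "anova_oneway",
    "TukeyResult",
    "tukey_hsd",
    "DriftReport",
    "feature_drift_report",
]


# ---------------------------------------------------------------------------
# Full-reference metrics
# ---------------------------------------------------------------------------

def compute_ssim(ref: GrayImage, test: GrayImage) -> float:
    """Single-scale structural similarity (SSIM) on [0, 255] intensities.

    Gaussian weighting window with sigma = 1.5 (11x11 support), standard
    stabilizers C1 = (0.01 L)^2, C2 = (0.03 L)^2 with L = 255, and the
    weighted population moments of the original formulation.  The
    similarity map border (half window) is cropped before averaging.
    """
    ref = as_gray_image(ref).astype(np.float64)
    test = as_gray_image(test).astype(np.float64)
    if ref.shape != test.shape:
        raise ValueError("images must be congruent")
    sigma, truncate = 1.5, 3.5
    L = 255.0
    C1 = (0.01 * L) ** 2
    C2 = (0.03 * L) ** 2
    f = lambda a: ndimage.gaussian_filter(a, sigma=sigma, truncate=truncate)
    ux, uy = f(ref), f(test)
    uxx, uyy, uxy = f(ref * ref), f(test * test), f(ref * test)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    cxy = uxy - ux * uy
    S = ((2 * ux * uy + C1) * (2 * cxy + C2)) / ((ux**2 + uy**2 + C1) * (vx + vy + C2))
    pad = int(truncate * sigma + 0.5)
    if S.shape[0] > 2 * pad and S.shape[1] > 2 * pad:
        S = S[pad:-pad, pad:-pad]
    return float(S.mean())


def compute_gmsd(ref: GrayImage, test: GrayImage) -> float:
    """Gradient magnitude similarity deviation (GMSD).

    Both images are low-passed with a 2x2 average filter and downsampled
    by 2, Prewitt gradients (kernels scaled by 1/3) give the gradient
    magnitudes, and the score is the population standard deviation of
    the pixelwise gradient-magnitude similarity map with stabilizer
    c = 170.  0 means identical gradient structure.
    """
    ref = as_gray_image(ref).astype(np.float64)
    test = as_gray_image(test).astype(np.float64)
    if ref.shape != test.shape:
        raise ValueError("images must be congruent")
    c = 170.0

    def down(a: np.ndarray) -> np.ndarray:
        sm = ndimage.uniform_filter(a, size=2, mode="nearest", origin=-0)
        return sm[::2, ::2]

    r, t = down(ref), down(test)
    px = np.array([[1, 0, -1], [1, 0, -1], [1, 0, -1]], dtype=np.float64) / 3.0
    py = px.T

    def gradmag(a: np.ndarray) -> np.ndarray:
        gx = ndimage.convolve(a, px, mode="nearest")
        gy = ndimage.convolve(a, py, mode="nearest")
        return np.sqrt(gx * gx + gy * gy)

    gr, gt = gradmag(r), gradmag(t)
    gms = (2 * gr * gt + c) / (gr * gr + gt * gt + c)
    return float(np.std(gms))


@dataclass(frozen=True)
class MetricPlugin:
    """A full- or no-reference scorer behind the uniform contract.

    ``fn(ref, test) -> float``; no-reference scorers simply ignore
    ``ref``.  ``identity`` is the score of an image against itself
    (1 for similarity metrics, 0 for distances); ``direction`` carries
    the report arrow ('higher-better' / 'lower-better').
    """

    name: str
    direction: str
    fn: object
    identity: float = 1.0


BUILTIN_METRICS: tuple[MetricPlugin, ...] = (
    MetricPlugin("SSIM", "higher-better", compute_ssim, identity=1.0),
    MetricPlugin("GMSD", "lower-better", compute_gmsd, identity=0.0),
)


@dataclass
class MetricReport:
    """Metric rows (name -> direction + per-method scores).

    A row whose plugin failed carries ``values=None`` and is marked
    unavailable rather than aborting the report.
    """

    rows: dict = field(default_factory=dict)

    def value(self, metric: str, method: str) -> float:
        return self.rows[metric]["values"][method]

    def to_dataframe(self):
        import pandas as pd

        records = {}
        for name, row in self.rows.items():
            arrow = "↑" if row["direction"] == "higher-better" else "↓"
            vals = row["values"] or {}
            records[f"{name} {arrow}"] = vals
        return pd.DataFrame(records).T

    def to_markdown(self) -> str:
        df = self.to_dataframe()
        header = "| Metric | " + " | ".join(df.columns) + " |"
        sep = "|" + "---|" * (len(df.columns) + 1)
        lines = [header, sep]
        for idx, row in df.iterrows():
            cells = " | ".join("" if np.isnan(v) else f"{v:.3f}" for v in row)
            lines.append(f"| {idx} | {cells} |")
        return "\n".join(lines)


def metric_report(
    ref: GrayImage,
    candidates: dict[str, GrayImage],
    metrics: tuple[MetricPlugin, ...] | list[MetricPlugin] = BUILTIN_METRICS,
) -> MetricReport:
    """Score every candidate against the reference with every metric."""
    ref = as_gray_image(ref)
    report = MetricReport()
    for plugin in metrics:
        values: dict[str, float] | None = {}
        for name, img in candidates.items():
            try:
                values[name] = float(plugin.fn(ref, as_gray_image(img)))
            except Exception:
                values = None
                break
        report.rows[plugin.name] = {
            "direction": plugin.direction,
            "values": values,
            "available": values is not None,
        }
    return report


def strip_experiment(
    img: GrayImage,
    col: int,
    width: int = 5,
    config: PipelineConfig | None = None,
    restorer=None,
    metrics: tuple[MetricPlugin, ...] | list[MetricPlugin] = BUILTIN_METRICS,
) -> MetricReport:
    """Cut a thin vertical strip, restore it three ways, score each.

    The strip (default 5 px wide) is excised from a defect-free image and
    treated directly as the defect core — its location is known, so no
    detection runs.  Candidates: ``background`` (inpainting only, the
    neural-network role), ``interpolation`` (per-row polynomials only),
    and ``overlay`` (the fused composite); ``original`` is the reference
    against itself.  Scores are computed on the whole image.
    """
    if config is None:
        config = PipelineConfig()
    img = as_gray_image(img)
    cut, _truth = cut_strip(img, col, width)
    if width == 0:
        candidates = {"original": img, "background": cut, "interpolation": cut, "overlay": cut}
        return metric_report(img, candidates, metrics)
    core = DefectCore(
        intervals={r: (col, col + width) for r in range(img.shape[0])}, connected=True
    )
    interp = interpolate_core(cut, core, degree=config.interp_degree, flank_k=config.flank_k)
    background = restore_background(cut, core, restorer=restorer)
    smask = streak_mask(
        interp, core, margin=config.mask_margin, mask_clip=config.mask_clip,
        threshold=config.mask_threshold, grid=config.grid,
    )
    composite = overlay(background, interp, smask)
    candidates = {
        "original": img,
        "background": background,
        "interpolation": interp,
        "overlay": composite,
    }
    return metric_report(img, candidates, metrics)


# ---------------------------------------------------------------------------
# Radiomics first-order features
# ---------------------------------------------------------------------------

FIRST_ORDER_NAMES: tuple[str, ...] = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)

#: Fixed bin width for the discretized features (Entropy, Uniformity);
#: the standard radiomics default for 8-bit intensity data.
BIN_WIDTH = 25


def first_order_features(
    img: GrayImage, mask: BreastMask | np.ndarray, bin_width: int = BIN_WIDTH
) -> dict[str, float]:
    """The 18 standard first-order radiomics descriptors over in-mask pixels.

    Discretized features use fixed-bin-width binning anchored at zero
    (bin index ``floor(x / bin_width)``), so shifting all intensities by
    a multiple of the bin width leaves Entropy and Uniformity unchanged.
    Kurtosis is the raw fourth standardized moment (not excess);
    Skewness and Kurtosis of a constant region are defined as 0.
    """
    img = as_gray_image(img)
    m = mask.mask if isinstance(mask, BreastMask) else np.asarray(mask, dtype=bool)
    if m.shape != img.shape:
        raise ValueError("mask not congruent with image")
    x = img[m].astype(np.float64)
    if x.size == 0:
        raise ValueError("empty mask")

    n = x.size
    mean = float(x.mean())
    var = float(x.var())
    std = float(np.sqrt(var))
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0

    counts = np.bincount((x.astype(np.int64) // bin_width))
    p = counts[counts > 0] / n

    if std > 0:
        skew = float(np.mean(((x - mean) / std) ** 3))
        kurt = float(np.mean(((x - mean) / std) ** 4))
    else:
        skew = kurt = 0.0

    energy = float(np.sum(x * x))
    return {
        "Energy": energy,
        "TotalEnergy": energy,  # unit pixel spacing
        "Entropy": float(-np.sum(p * np.log2(p))),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt(np.mean(x * x))),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": float(np.sum(p * p)),
    }


@dataclass
class FeatureTable:
    """Per-group feature values: feature name -> {group -> list of values}.

    All groups must hold the same number of images (the drift statistics
    assume balanced groups) and the 18 first-order names are always
    present; texture features supplied by a plugin extractor are simply
    additional rows.
    """

    groups: list[str]
    features: dict[str, dict[str, list[float]]]

    def __post_init__(self) -> None:
        counts = set()
        for name, per_group in self.features.items():
            if set(per_group) != set(self.groups):
                raise ValueError(f"feature {name!r} missing some groups")
            counts.update(len(v) for v in per_group.values())
        if len(counts) > 1:
            raise ValueError("groups must have equal image counts")
        missing = set(FIRST_ORDER_NAMES) - set(self.features)
        if missing:
            raise ValueError(f"first-order features missing: {sorted(missing)}")


def build_feature_table(
    images_by_group: dict[str, list[GrayImage]],
    masks_by_group: dict[str, list[np.ndarray]] | None = None,
    texture_extractor=None,
    bin_width: int = BIN_WIDTH,
) -> FeatureTable:
    """Compute a FeatureTable from images (plus optional masks).

    ``texture_extractor(img, mask) -> dict[str, float]`` is the
    pluggable contract for texture features; without it the table holds
    the 18 first-order rows only.
    """
    groups = list(images_by_group)
    features: dict[str, dict[str, list[float]]] = {}
    for g in groups:
        imgs = images_by_group[g]
        masks = masks_by_group[g] if masks_by_group else [np.ones_like(im, bool) for im in imgs]
        for img, m in zip(imgs, masks):
            vals = first_order_features(img, m, bin_width=bin_width)
            if texture_extractor is not None:
                vals.update(texture_extractor(img, m))
            for name, v in vals.items():
                features.setdefault(name, {gg: [] for gg in groups})[g].append(float(v))
    return FeatureTable(groups=groups, features=features)


# ---------------------------------------------------------------------------
# ANOVA and Tukey HSD
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    """One-way ANOVA for one feature: F, p, and the group means."""

    F: float
    p: float
    group_means: dict[str, float]


def anova_oneway(samples: dict[str, list[float]]) -> AnovaResult:
    """Classical one-way ANOVA (null: all group means equal).

    Degenerate inputs are resolved explicitly: zero within-group and
    zero between-group variance gives F = 0, p = 1; zero within-group
    variance with distinct means gives F = inf, p = 0 (below the machine
    floor).
    """
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=np.float64) for k, v in samples.items()}
    if any(a.size < 2 for a in arrays.values()):
        raise ValueError("each group needs at least two values")
    means = {k: float(a.mean()) for k, a in arrays.items()}
    ssw = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays.values())
    grand = np.concatenate(list(arrays.values())).mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays.values())
    if ssw == 0.0:
        if np.isclose(ssb, 0.0):
            return AnovaResult(F=0.0, p=1.0, group_means=means)
        return AnovaResult(F=np.inf, p=0.0, group_means=means)
    F, p = sstats.f_oneway(*arrays.values())
    return AnovaResult(F=float(F), p=float(p), group_means=means)


@dataclass
class TukeyResult:
    """Tukey HSD for one feature over balanced groups.

    ``q[(i, j)]`` is the studentized-range statistic
    |X̄i − X̄j| / sqrt(σk²/n) with σk² the pooled within-group mean
    square and n the common group size; ``p[(i, j)]`` its p-value from
    the studentized-range distribution with k groups and N − k degrees
    of freedom.  Pairs with p < 0.05 are flagged significant.
    """

    groups: list[str]
    n: int
    msw: float
    q: dict[tuple[str, str], float]
    p: dict[tuple[str, str], float]
    significant: set = field(default_factory=set)

    def pair(self, i: str, j: str) -> tuple[float, float]:
        key = (i, j) if (i, j) in self.q else (j, i)
        return self.q[key], self.p[key]


def tukey_hsd(samples: dict[str, list[float]], alpha: float = 0.05) -> TukeyResult:
    """Tukey honestly-significant-difference test on balanced groups."""
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=np.float64) for k, v in samples.items()}
    sizes = {a.size for a in arrays.values()}
    if len(sizes) != 1:
        raise ValueError("Tukey HSD requires balanced groups (equal n)")
    n = sizes.pop()
    if n < 2:
        raise ValueError("each group needs at least two values")
    k = len(arrays)
    N = k * n
    msw = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays.values()) / (N - k)
    labels = list(arrays)
    q: dict[tuple[str, str], float] = {}
    p: dict[tuple[str, str], float] = {}
    sig = set()
    for a_i in range(k):
        for b_i in range(a_i + 1, k):
            i, j = labels[a_i], labels[b_i]
            diff = abs(arrays[i].mean() - arrays[j].mean())
            if msw == 0.0:
                qv = 0.0 if np.isclose(diff, 0.0) else np.inf
                pv = 1.0 if qv == 0.0 else 0.0
            else:
                qv = float(diff / np.sqrt(msw / n))
                pv = float(sstats.studentized_range.sf(qv, k, N - k))
            q[(i, j)] = qv
            p[(i, j)] = pv
            if pv < alpha:
                sig.add((i, j))
    return TukeyResult(groups=labels, n=n, msw=msw, q=q, p=p, significant=sig)


# ---------------------------------------------------------------------------
# Feature drift report
# ---------------------------------------------------------------------------

@dataclass
class DriftReport:
    """Which features drifted, per method, against the original group."""

    original: str
    methods: list[str]
    anova_p: dict[str, float]
    tukey_flag: dict[str, dict[str, bool]]  # feature -> method -> drifted?
    percent_drifted: dict[str, dict[str, float]]  # panel -> method -> %


def feature_drift_report(
    table: FeatureTable, original: str | None = None, alpha: float = 0.05
) -> DriftReport:
    """ANOVA + Tukey HSD drift summary across image groups.

    For every feature the group means are compared with one-way ANOVA;
    each (original, method) pair is tested with Tukey HSD and flagged
    when p < ``alpha``.  The summary gives the percentage of flagged
    features per method, split into first-order and texture panels.
    """
    if original is None:
        original = table.groups[0]
    if original not in table.groups:
        raise ValueError(f"unknown original group {original!r}")
    methods = [g for g in table.groups if g != original]
    anova_p: dict[str, float] = {}
    tukey_flag: dict[str, dict[str, bool]] = {}
    for name, per_group in table.features.items():
        anova_p[name] = anova_oneway(per_group).p
        tk = tukey_hsd(per_group, alpha=alpha)
        tukey_flag[name] = {
            m: tk.pair(original, m)[1] < alpha for m in methods
        }
    panels = {
        "first-order": [f for f in table.features if f in FIRST_ORDER_NAMES],
        "texture": [f for f in table.features if f not in FIRST_ORDER_NAMES],
    }
    percent: dict[str, dict[str, float]] = {}
    for panel, names in panels.items():
        if not names:
            continue
        percent[panel] = {
            m: 100.0 * sum(tukey_flag[f][m] for f in names) / len(names) for m in methods
        }
    return DriftReport(
        original=original,
        methods=methods,
        anova_p=anova_p,
        tukey_flag=tukey_flag,
        percent_drifted=percent,
    )
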