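# Methods

## The defect model

The pipeline targets a specific detector-fault signature on 8-bit
mammograms: a vertical band in which intensity rises sharply — up to
saturation at 255, destroying the signal — flanked by a smooth intensity
ramp that decays with distance, an intensity *drop* on the opposite side
of the band, and a loss of contrast on one half of the image. Band width
and intensity are anticorrelated in practice (wide bands are dim, narrow
bands are bright), and the band's brightness varies along its length, so
the destroyed "core" may be absent in some rows. The algorithm assumes
exactly one such band per image, oriented vertically, and that at least
one side of the image retains normal contrast.

## Pipeline stages and their parameters

| Parameter | Default | Meaning |
|---|---|---|
| `low_thresh` | 5 | contour scan stops once intensity exceeds this (8-bit units) |
| `hi_thresh` | 220 | core pixels are strictly above this, or exactly 0 |
| `tile` | 100 px | flank tile size for baseline flattening |
| `extent_layers` | 4 | tile layers (columns of tiles) flattened per side |
| `grid` | 8 | CLAHE tiles per axis |
| clip-limit floor | 0.1 | keeps the adaptive clip limit positive |
| `interp_degree` | 1 | per-row interpolation polynomial degree |
| `flank_k` | 3 | flank columns averaged into each interpolation anchor |
| `mask_clip` | 20 | CLAHE clip limit for streak-mask extraction |
| `mask_threshold` | 170 | incomplete-thresholding cut (informative = 171–255) |
| `mask_margin` | 50 px | streak mask window margin beyond the core |
| `feather` | 20 px | linear blend width at the equalized-side seam |

**Core detection.** The 220/0 test is applied to the raw 8-bit input
(before any normalization). When a row contains several disjoint
qualifying runs, the run whose center is nearest the median core column
is kept: the defect is a single vertical structure, stray bright specks
are noise. Gap rows between the topmost and bottommost detected rows get
interval bounds linearly interpolated in row index, rounded half-up; the
operation is idempotent and never shrinks an interval.

**Ramp flattening.** Each flank tile's per-column means are corrected
toward a straight baseline drawn from the minimum column mean on the
illuminated side to the maximum on the darkened side. The darkened-side
anchor is taken from the paired tile across the core (the correction
window spans both sides); a mask-clipped tile without a partner falls
back to its own extreme column means, which leaves flat and affine
regions untouched. Subtracting (mean − baseline) per column makes the
post-correction column means equal the baseline exactly up to integer
rounding and 0/255 clipping. Note the baseline is a straight line: a
curved ramp is linearized per tile, not forced flat; the residual slope
shrinks with each additional tile layer and vanishes when the ramp's
support fits within the tiled extent.

**Contrast equalization.** The two sides of the band are characterized
by the histogram mode (ties broken toward the smaller intensity, for
determinism) and the population standard deviation of in-breast,
non-core pixels. The side with the larger deviation is the reference
("A"); CLAHE with `clip_limit = 1.11 − 0.023·(stdB − stdA)` is applied
to side B only, on the bounding box of its in-breast pixels with the
background filled by the side median so black pixels do not skew tile
histograms, and blended back with a 20-column linear feather at the core
boundary. The regression for the clip limit is taken as given (it was
fit on clinical data that is not available); on synthetic phantoms with
a 2× contrast reduction it raises the low side's deviation by roughly a
third — it narrows the contrast gap rather than closing it, because the
formula's output stays near 1.1, a conservative clip.

**CLAHE semantics.** The clip limit is on the conventional "multiples of
the uniform histogram level" scale: the per-tile clip in counts is
`clip_limit · tile_area / 256`, with uniform redistribution of the
excess and bilinear interpolation between the 8 × 8 tile LUTs. A tile
with zero dynamic range maps through the identity LUT, so constant
regions are exact fixed points. Outputs are rounded half-up; all
rounding in the package is half-up for cross-platform reproducibility.

**Core restoration and fusion.** Degree-1 interpolation fits a line per
core row through two anchors, each the mean value (at the mean column
position) of the 3 columns immediately flanking the interval; averaging
resists pixel noise at the cost of slightly diluting thin streaks.
Degrees 2–3 least-squares-fit the individual flank pixels; on smooth
flanks they differ from degree 1 by only a few intensity units, and
higher degrees are rejected as artifact-prone. The background restorer
is a contract — congruent output, bit-identical outside the hole — with
two implementations: classical biharmonic inpainting at full resolution,
and a coarse–fine adapter that fills at 1/16 of the short image
dimension, refines at 1/8 (on a ~4000-px mammogram these reproduce the
conventional 256/512 working sizes), and sharpens the fill by adding the
contextual residual — the detail lost by a down/up-sample round trip —
transferred from the nearest out-of-hole pixel. That nearest-neighbour
transfer is a deliberately simple stand-in for learned attention-based
structure transfer; training or bundling a neural network is out of
scope. The streak mask thresholds the CLAHE-boosted (clip 20, same 8 × 8
grid) interpolated window at 170, and the composite selects interpolated
pixels where the mask is set, background pixels elsewhere. With no
detectable core the pipeline bypasses restoration and returns the
contrast-equalized input, partitioning the sides at the breast's median
column.

## The phantom generator

Phantoms emulate the morphology the algorithm assumes: a breast-shaped
half-ellipse flush with the left edge (~60% of the frame) on black
background; smooth tissue texture (value noise, correlation length 8 px,
amplitude 6); a dense layer of fine fibrous strands (35 per image,
10–30 units bright) plus a few prominent vessel-like streaks (5 per
image, 30–60 units, ~3 px wide) drawn as random chords with a sinusoidal
bow, so they cross a vertical band transversally as often as not; and an
injectable band defect with saturating gain, raised-cosine flank ramps
(default extent 150 px; the true defect's flank shape is not documented,
so the generator owns it), an opposite-side intensity drop, and a
one-sided linear contrast reduction about the side mean with optional
blur. Everything derives from one explicitly seeded generator;
identical specs give bit-identical images.

What the phantom does *not* model: X-ray physics, dose and scatter,
lesions and masses, pectoral muscle, skin line, pixel-scale quantum
mottle, and the full multi-scale texture statistics of fibroglandular
tissue. Consequently, tests passing on phantoms show that the pipeline's
mechanics (detection geometry, flattening arithmetic, mask semantics,
locality) are correct, not that clinical image quality gains carry over.

## The fusion-dominance caveat

On clinical imagery the composite is reported to outscore both of its
sources, because their failure modes are complementary there: a heavily
resolution-limited background restorer blurs streaks (which the mask
selects from the interpolation), while interpolation leaves banding in
the textured background (which the mask leaves to the background
restorer). On these phantoms that regime does not arise: at a 5-px
excised strip, classical full-resolution inpainting alone is already
within ~1–2 intensity units of ground truth, the locally-brightest-third
mask does not predict where interpolation is the better source
(alignment is near chance), and hard mask switching adds seam gradients.
The composite therefore scores between its two sources rather than above
both. With an oracle mask the dominance is recovered by construction, so
the limitation is the brightness-as-proxy premise at this scale, not the
overlay operator. The seeded ordering suite is kept as-is and documents
this gap honestly.

## Statistics

One-way ANOVA is classical (between/within mean squares, F
distribution); degenerate inputs are resolved explicitly (all-equal
data → F = 0, p = 1; zero within-group variance with distinct means →
F = ∞, p reported as 0). Tukey HSD requires balanced groups and uses
`Q = |X̄i − X̄j| / sqrt(MSW/n)` with MSW the pooled within-group mean
square, p-values from the studentized-range distribution with N − k
degrees of freedom. The 18 first-order radiomics descriptors follow the
standard definitions (kurtosis is the raw fourth standardized moment,
not excess; skewness and kurtosis of a constant region are defined as
0); discretized features (entropy, uniformity) use fixed bin width 25
anchored at zero, so shifting intensities by a bin-width multiple leaves
them invariant. Texture features are a pluggable extractor contract with
no built-in implementation.

## Problem sizes

The seeded suites use 512 × 512 phantoms: 20 seeds for band-parameter
recovery and for the cut-strip ordering experiment, 10,000 replicates
for the ANOVA type-I calibration. These sizes give stable statistics
(binomial standard error ≈ 0.002 on the calibration) while a full run of
tests plus the acceptance script stays under a minute of compute.
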