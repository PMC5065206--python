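# Methods

This note records the scientific and numerical choices behind `nucmorph`:
what each component computes, the parameters that matter, what the
synthetic data do and do not emulate, and the known limitations.

## Geometry

Coordinates are `(x, y) = (column, row)`, 0-based, pixel centers at
integers. A contour is the ordered outer boundary of a single 8-connected
nucleus region, traced with Moore-neighbor tracing (Jacob's stopping
criterion) from the topmost-leftmost boundary pixel. The traced point set
is the standard perimeter-pixel set — foreground pixels with a 4-connected
background neighbor. Pixels whose only background contact is diagonal are
deliberately not part of the path: routing through every such inner corner
would turn the chain into a city-block path, inflating the perimeter of a
digitized circle by ~27% and distorting every downstream shape score.
Holes are ignored (the segmenter fills them anyway).

The centroid is the arithmetic mean of the *contour points*, not of the
filled region. For convex, roughly isotropic nuclei the two differ by a
small fraction of a pixel; using the contour mean keeps every score a
function of the boundary alone, so contours loaded from CSV need no mask.

Two perimeter estimators are provided. The raw chain length (1 per axial
step, √2 per diagonal) is exact for polygonal paths but systematically
~5% long for digitized smooth curves, independent of radius — a digital
straight line at angle θ is measured as `|dx−dy| + √2·min(dx,dy)`, which
exceeds the Euclidean length except at multiples of 45°. The shape metrics
therefore use the Vossepoel–Smeulders corrected weights (0.948 axial,
1.340 diagonal), which bring a digitized circle within ~1% of `2πr` and
make SF of digital disks land at 0.99–1.00 instead of ~1.10.

## Segmentation

The pipeline for a pre-cropped single-cell frame: RGB → luminance
(0.299/0.587/0.114, rounded to 8 bits) → classic 256-bin cumulative
histogram equalization (constant images pass through) → Sobel gradient
magnitude (edge replication at borders) → band threshold → region cleanup.

The band threshold computes the gradient image's mean and standard
deviation and keeps pixels with gradient in `[mean−std, mean+std]`; if the
whole image already lies in that band, it instead keeps pixels within
`ε = 0.5` gray levels of the mean (the nearest-integer reading of
"equal to the mean" on a float gradient). Flat regions — nucleus interior
and surrounding cytoplasm — fall inside the band; the strong edge ring
around the nucleus falls above it and separates the two.

Region cleanup selects the largest 8-connected in-band component, then
applies morphological closing (disk, radius 3 px, configurable) and hole
filling. Selection happens *before* closing: the nucleus and background
components are separated only by the thin excluded edge band, and closing
the raw candidate mask dilates both regions across that band and merges
them, after which the "largest component" is the whole frame. Closing the
already-selected region keeps its purpose — repairing small holes and
intrusions in the nucleus — without that failure mode.

The method presumes the nucleus is the dominant flat region in the frame,
i.e. tightly cropped single-cell images; it is not a multi-cell scene
segmenter.

## Penalty-driven smoothing score

The moving-average filter uses circular wraparound: the radial profile is
a closed curve, and wraparound is the only boundary policy under which the
score is invariant to where the trace happened to start. A `shrink`
option reproduces the window-shrinking endpoint convention of common
sequence smoothers for comparison, but is not the default.

Ratio bins are half-open — `[0, 0.1)`, `[0.1, 0.2)`, `[0.2, 0.3)`,
`[0.3, ∞)` — so each point lands in exactly one bin and the fractions sum
to 1 (required for PD to interpolate between c₁ and c₄). A perfectly
smooth profile has zero mean deviation; its ratios are defined as 0 and
the score collapses to c₁. Contours are not resampled to a fixed N; the
score is a per-point average, so N only sets resolution.

Two structural properties shape how PD behaves and are worth stating
explicitly. First, PD is *scale-free*: deviations are normalized by their
own mean, so uniformly larger bumps do not raise the score — PD responds
to the shape of the deviation distribution (diffuse, noise-like deviations
spread the ratios and raise PD; a few large spikes inflate the mean and
compress everything else into the low bins, lowering it). Second, because
pixel quantization already contributes diffuse sub-pixel deviations, a
digitized circle scores ~2.5 (linear, span 3) rather than the analytic
minimum of 1.0. Both effects mean PD is a comparative score between
contours digitized the same way, not an absolute irregularity measure.
A consequence reproduced by the synthetic cohort: the class ranking by PD
*reverses* between span 3 (smooth class lowest) and spans 7–9 (smooth
class highest), because larger spans cannot track any structure and every
profile's deviation distribution drifts toward the diffuse regime. At the
intermediate span 5 the cubic-weighted variant sits at the crossing and
does not separate the smooth from the mildly dysplastic class — an
intrinsic blind spot of the span/penalty grid, matching the method's
behavior of having some non-discriminating combinations.

## Residual-based analysis

Mean-type: residuals about the mean radius. Median-type: residuals about
the median (even-N median = average of the two middle order statistics —
the printed "(N+1)/2-th sorted value" is only defined for odd N). σ uses
the N−1 denominator. The scores are in pixels and scale linearly with
magnification; comparisons require a consistent imaging protocol.

## Comparison metrics

RA inscribes the largest *centroid-centered* circle — radius equal to the
minimum centroid-to-contour distance — and reports the fraction of nucleus
pixels strictly outside it. Note the discretization floor: the innermost
boundary pixel sits up to ~1 px inside the true boundary, so a digital
disk of radius r has RA ≈ 2/r (0.10 at r = 20, 0.04 at r = 45), not 0.
RD is implemented as the absolute perimeter excess `P − 2√(πA)`; a
dimensionless ratio variant `P / 2√(πA)` is available behind a flag. RD
and SF are co-monotone at fixed area (`RD > 0 ⟺ SF > 1` algebraically).

## Statistical protocol

Scores are compared across the three diagnostic classes with a Friedman
test (within-block ranks, rank 1 = lowest score, average ranks for ties,
tie-corrected chi-square with k−1 df), followed when the omnibus test
rejects at α by pairwise z-tests on mean-rank differences,
`z = (R̄_i − R̄_j)/√(k(k+1)/6n)`, adjusted by Holm (step-down), Shaffer
(static step-down with the logically-possible-truths multiplier sequence;
(3,1,1) for k = 3), and Bergmann–Hommel (dynamic, via exhaustive-set
enumeration over group partitions, limited to k ≤ 5). For k = 3 the
Bergmann–Hommel and Shaffer adjustments coincide, and both are bounded by
Holm; all are bounded below by the raw p.

The images in each class are unpaired, yet the Friedman test is blocked.
Blocks are formed by pairing the i-th image of each class after a seeded
per-class shuffle (equal class sizes required). With exchangeable rows
this random pairing leaves the test's level intact (verified by the null
calibration below); a Kruskal–Wallis + Dunn escape hatch is provided for
users who prefer an unpaired test, clearly marked as a deviation from the
reference protocol. An Iman–Davenport F transform of the Friedman
statistic is available behind a flag.

## Synthetic data

A nucleus boundary is a star-shaped polar curve: ellipse base radius,
plus cosine harmonics (waviness), minus Gaussian angular dips (notches,
i.e. localized indentations), plus optional white radial jitter; sampled
at ~1 px arc length, polygon-filled, and re-traced to a pixel contour.
The three class distributions follow the Bethesda descriptions: NILM —
smaller (radius 35–55 px at a nominal 100× oil-immersion scale),
near-round, no notches, minimal jitter; LSIL — enlarged (55–80 px), wavy,
1–3 narrow notches; HSIL — enlarged (60–85 px), higher-frequency waviness,
2–4 deeper notches, more jitter. Class ranges overlap by design, so the
two dysplastic classes' score distributions overlap substantially while
both separate from NILM — the qualitative pattern the statistical
protocol is meant to exhibit. The class parameters are part of the
package's fixed study conditions; they were calibrated once to that
documented pattern and are not tuned per run.

Rendering emulates a cropped micrograph: dark nucleus (60) on lighter
cytoplasm (180), a smooth random intensity field (std 18 gray levels,
correlation length 12 px) for chromatin/illumination inhomogeneity, white
sensor noise (σ = 5), and a tight frame margin (0.10 of the equivalent
radius). The texture field is not cosmetic: a strictly two-level image
has a degenerate histogram, and equalizing it amplifies sensor noise into
gradients comparable to the nucleus edge, which defeats any gradient-band
threshold; real micrographs have spread histograms and equalize gently.
The defaults sit in the middle of a wide parameter plateau, not on a
knife-edge.

What the synthetic data do *not* emulate: chromatin texture inside the
nucleus beyond a smooth field, overlapping or touching cells, stain
variation, out-of-focus blur, and non-star-shaped (self-folding) nuclear
outlines. Passing tests on this cohort show that the scores and the
protocol behave as designed on controlled geometry; they do not certify
clinical performance on stained slides.

## Problem sizes and numerics

The reference cohort is 200 nuclei per class (one fixed master seed), the
size at which the three-class pattern is assessed. Null calibration uses
100 independent cohorts of 50 per class, all classes drawn from the NILM
distribution, and checks the Friedman rejection rate at nominal α = 0.05;
50 per class is enough because the test's level does not depend on n at
these sizes. The segmentation round-trip uses 100 rendered nuclei cycling
through the three classes. Oracle-equivalence checks run 50 random
contours against straight-line reimplementations (PD to 1e-9, residuals
to 1e-12). Random draws use `numpy.random.default_rng` throughout;
every public entry point takes an explicit seed.

## Known limitations

- PD's scale-freeness makes it insensitive to overall irregularity
  amplitude and leaves the span-5/cubic variant non-discriminating on the
  synthetic cohort (see above).
- The segmenter requires a single nucleus dominating a tightly cropped
  frame and a histogram with some spread; it fails (by design, with an
  error) on constant images and can latch onto the background if the
  nucleus occupies a minority of the frame.
- Residual scores are in pixels; cross-magnification comparisons require
  rescaling.
- The seeded-shuffle blocking is one arbitrary pairing of unpaired
  groups; a different seed gives a slightly different p-value (the
  reported results fix the seed for exact reproducibility).
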