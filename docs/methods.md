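# Methods

This note records the models, algorithms and design choices behind
`rgcquant`, in the order data flows through the pipeline.

## Synthetic whole-mount model

A simulated retina is a disc-shaped tissue footprint with four symmetric
radial relief cuts (wedge notches, depth 25% of the radius, ~4° half-angle
at the rim, at the diagonal display angles), mimicking the cuts made when a
retina is flattened. The disc radius is solved analytically so that the
footprint area *after* the cuts equals the preset's retinal area; the
optic nerve head (ONH) sits at the disc centre and the dorsal direction is
recorded as an angle in the sidecar metadata (90° = up on the display),
never inferred from pixels.

**Species presets.** Each preset carries retinal area (mm²), uninjured
target density (cells/mm²), soma-size distribution, gradient, injury
course, and (young killifish only) fractional area growth per day. The
four built-ins encode the published whole-retina means for mouse 10 w,
zebrafish 21 w and killifish 6/18 w (densities 3,179 / 17,390 / 17,769 /
14,041 cells/mm²; counts 44,499 / 66,262 / 74,597 / 132,159), with areas
derived as count ÷ density. Soma sizes are not published numerically;
defaults are mouse 12 ± 1.5 µm and fish 6.5 ± 1.0 µm FWHM, preserving the
qualitative size contrast at a detectable scale. Young-killifish growth
defaults to 0.004/day (~8.4% over 21 days); its true magnitude is not
published and the parameter is free.

**Injury courses.** Survival fraction vs. days post crush is
piecewise-linear between anchors, constant beyond the last anchor:
mouse {0: 1, 7: 0.41, 14: 0.19}; zebrafish {0: 1, 7: 1, 14: 0.97,
21: 0.88}; killifish 6 w {0: 1, 4: 0.79, 7: 0.79, 14: 0.67, 21: 0.67};
killifish 18 w {0: 1, 4: 0.83, 7: 0.83, 14: 0.56, 21: 0.56}. The expected
cell count of a simulated retina is footprint area × (1 + growth·dpi) ×
target density × survival(dpi); the realized count is a Poisson draw from
that mean. Uninjured age-matched controls are generated at the same
chronological day with the survival term fixed at 1, so growth cancels in
the survival normalization.

**Cell placement.** RGCs tile the retina as a semi-regular mosaic with an
exclusion zone; the generator emulates this directly. A hexagonal lattice
with random pose is built with enough node headroom that even the gradient
peak occupies ≤ 85% of nodes; nodes are jittered inside a disc sized so the
hard-core minimum separation (0.8 × mean soma diameter) is guaranteed, then
thinned with probability proportional to the local target intensity, and
the selection is adjusted to exactly the Poisson-drawn count. A random
sequential (dart-throwing) hard-core process cannot reach these conditions:
at the fish presets' packing fractions the gradient peak sits near the
jamming density, so counts fall short and the configured contrast
collapses — the mosaic construction delivers both exactly.

**Density gradient.** Fish presets peak ventrotemporally. The placement
intensity is 1 + a·cos(φ) with φ the display angle from the VT-quadrant
bisector and *a* solved so that the mean intensity over the peak quadrant
divided by the opposite quadrant equals the preset contrast (default 1.6);
the quadrant mean of cos over a 90° wedge is 2√2/π. Mouse is uniform.

**Rendering.** Each soma is a 2-D Gaussian spot with FWHM equal to its
diameter draw, placed at its continuous sub-pixel position (sigma quantized
to 0.1 px for vectorized stamping); amplitude is peak-SNR × noise-sigma
(default peak SNR 10) with 10% per-cell brightness jitter emulating
staining heterogeneity; background is constant plus Gaussian noise; the
image is written as 16-bit grayscale. Default rendering pixel size is
1 µm/px; generation refuses calibrations that leave the mean soma FWHM
below 2 px. Identical arguments and seed give bit-identical output. Not
modelled: axon bundles, vasculature, 3-D structure, multi-channel stains,
uneven illumination, and dissection damage beyond the relief cuts — so
passing tests demonstrate correctness of the measurement chain under
idealized staining, not robustness to every real-world artifact.

## Segmentation

Gaussian smoothing at 20 µm (well above soma scale) → Otsu threshold →
morphological closing with a 50 µm disc (below the relief-cut width, so
clefts stay open and do not inflate the area) → largest connected
component → hole filling. Morphology runs on a ~4 µm/px working grid; the
20 µm pre-smoothing makes the decimation alias-free, and rim quantization
is below half a working pixel. A signal-free guard rejects frames whose
Otsu class separation is within 5× the noise floor expected after
smoothing (noise estimated from row-difference MADs). Area is exactly
foreground-pixel count × pixel-size² / 10⁶.

## Soma detection

Densely packed fish retinas put nearest neighbours at ~2× the soma
Gaussian width, where single-scale blob detection merges cells (measured
recall 0.67–0.87 with a standard multiscale Laplacian-of-Gaussian detector
at these packing fractions). The engine therefore works in two stages:

1. **Sharpen + peaks.** After a Gaussian high-pass at 5× the maximum soma
   diameter, the image is deconvolution-sharpened by a Wiener-regularized
   inverse Gaussian filter at `scales` (default 3) widths spanning
   0.65–1.0× the mean soma sigma (slightly under-matched PSFs resolve
   near-hard-core pairs best; regularization `wiener_eps` = 10⁻³). 3 × 3
   local maxima of every scale inside the mask are pooled; an Otsu split
   of the candidate responses isolates the soma-like class and candidates
   below `intensity_quantile` (0.5) × median(soma-class response) are
   dropped; greedy non-maximum suppression enforces the minimum separation
   (ties: stronger response, then lower y, x), and peaks are localized to
   sub-pixel accuracy by parabolic fits.
2. **Matching pursuit.** Gaussian spots with jointly estimated amplitudes
   (clamped Jacobi iterations on the peak-value system) are subtracted and
   the residual re-searched with a descending gate (0.8, 0.7, … 0.35 × the
   pass-1 gate). Residual candidates must sit adjacent to an existing
   detection (within 1.5 mean diameters — an occluded soma is next to its
   occluder by construction) and in a crowded neighbourhood (≥ 8
   detections within 2.2 mean diameters — blending only happens near
   mosaic packing; looser neighbourhoods yield ring artifacts and noise).
   The descent stops once a pass's yield stops shrinking, the signature
   that the residual is down to noise.

Every threshold is relative to the response distribution, so the count is
invariant to affine intensity rescaling, and everything is deterministic.
Species defaults: soma diameter range 8–16 µm (mouse) and 4–9 µm (fish);
minimum separation 0.8× the range minimum for mouse and 4.0 µm for fish
(~0.6× mean diameter — fish mosaics never place somata closer than 5.2 µm,
so the wider radius suppresses duplicate peaks without losing true pairs).
On generator output at default noise this yields precision/recall ≥ 0.95
and total counts within ~2% for all four presets (measured in the test
suite).

## Density and quadrants

Whole-retina density is count ÷ area. The isodensity map evaluates
ρ(u) = 10⁶ · N⁻¹Σᵢ … — concretely N × pdf × 10⁶ — on a grid (default
25 µm spacing = σ/4) over the mask bounding box: exactly (direct kernel
sum) for small problems, and by nearest-node binning + FFT convolution
with the exactly-evaluated kernel for large ones (binning displaces cells
by ≤ spacing/√2; the kernel is truncated at 6σ). No boundary correction is
applied, so values within ~2σ of the rim underestimate — a known bias
shared with the standard procedure. The map integrates to N within 1%
whenever cells sit ≥ 3σ inside the boundary.

Quadrants are the four 90° sectors around the ONH bounded by the dorsal,
nasal, ventral and temporal axes; labels (DN/DT/VN/VT) follow eye
chirality via `nasal_side`, boundaries are half-open (a point on an axis
belongs to the counter-clockwise sector), and the dorsal angle comes from
sidecar metadata or user input. Per-quadrant counts and areas sum exactly
to the totals because every centroid and mask pixel receives exactly one
label. How the original analyses oriented their quadrant axes is not
stated anywhere; here it is an explicit parameter.

## Survival normalization

Survival is computed from densities, not raw counts, for all species
(published analyses state this explicitly only for killifish; densities
cancel dissection artifacts and growth, so the choice is extended
uniformly): each retina's density is expressed as a percentage of the
median density of uninjured age-matched controls of the same species/age
stratum, with per-quadrant survival normalized quadrant-to-quadrant.
Controls are sampled at the chronological endpoint of the cohort, so
young-killifish growth cancels exactly. The uninjured group is
self-normalized, hence its median is exactly 100%.

## Statistics

Routing: every group is screened with Shapiro–Wilk (α = 0.05, not stated
in the source analyses); if any group fails, medians with Kruskal–Wallis
(tie-corrected, χ² reference) and all-pairs two-sided Mann–Whitney U with
Bonferroni multiplication (capped at 1); otherwise means with Welch
unequal-variance one-way ANOVA (Satterthwaite df) and Games–Howell pairs
(Welch-type pairwise t against the studentized range, which must match
published critical-value tables to two decimals — verified in the tests).
Mann–Whitney uses the exact null distribution for small untied samples and
the tie/continuity-corrected normal approximation otherwise; the plain
approximation deviates from exact enumeration by up to ~0.04 at n = 3–4,
which would violate the package's own 0.02 agreement bound. "Two-way
Kruskal–Wallis" is not a canonical procedure; the crossed age × time
analysis is implemented as Scheirer–Ray–Hare (rank-transformed two-way
ANOVA, each effect's SS divided by the total rank mean square, χ²
reference) — the closest standard rank-based two-factor test.

## Detector acceptance protocol

Counting engines are accepted the way trained counters are accepted
against human annotators: 177 × 177 µm frames sampled equally from the
central, mid and peripheral retina (equal thirds of normalized ONH-to-rim
distance, frames wholly inside the mask), per-frame model counts regressed
against reference counts by OLS; acceptance requires slope ∈ [0.9, 1.1],
R² ≥ 0.9 and R² ≥ inter-counter R² − 0.05 (the numeric thresholds stand in
for an unquantified "comparable"). Two synthetic counters are emulated as
ground truth corrupted by independent 2% miss and 1% spurious rates. Two
geometry-driven choices: frame tallies quoted per published dataset pool
several retinas, and a single mount's central third cannot host 16
disjoint frames — placement therefore prefers disjoint frames and relaxes
the centre spacing only when a stratum is too small; and the 36-frame
testing set pools 18 frames from an uninjured and 18 from an injured
whole-mount, because a uniform-density uninjured mouse gives only Poisson
spread in frame counts, leaving the regression noise-dominated and the
protocol uninformative.

## Problem sizes

Full-size simulations (mouse 14.0 mm², old killifish 9.4 mm² at 1 µm/px)
are used where absolute totals matter: the acceptance script's density and
count experiments run 5 seeded full-size retinas per preset. Survival
cohorts (n = 8/group) and the test suite run on area-reduced preset
variants (8–20% of full area; identical densities, soma sizes, gradients
and courses) — survival percentages, densities, precision/recall and all
conservation properties are per-unit-area quantities that do not depend on
the footprint, and the reduced sizes keep the whole suite and the
acceptance script desk-scale on a single core. Tolerances are never
adjusted for the reduced sizes.

## Known limitations

- The generator's idealizations (listed above) bound what the recovery
  experiments demonstrate; in particular the detector's Otsu-anchored gate
  assumes a unimodal soma brightness distribution (10% jitter) and may
  need re-tuning for strongly heterogeneous labels such as retrograde
  tracers.
- KDE maps carry the uncorrected rim bias.
- The Scheirer–Ray–Hare reading of "two-way Kruskal–Wallis" and the
  acceptance thresholds are this package's explicit choices where the
  source procedures are under-specified.
- Segmentation is tuned for single-channel images whose background is
  dark; it delegates nothing to learned models.
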