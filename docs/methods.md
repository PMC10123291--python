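# Methods

This note documents the models implemented in `micromorph`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical decisions that affect results.

## Morphometry

**Inputs.** A 2-D integer label raster (0 = background, k = cell id) with
a pixel size in µm, optionally a paired intensity raster. Segmentation is
an input, not a task of this package: in the motivating workflow microglia
are delineated from immunostained maximum-intensity projections.

**Perimeter.** The cell boundary is extracted as the sub-pixel
marching-squares contour at level 0.5 and lightly smoothed along its arc
with a periodic Gaussian (`contour_smooth_sigma`, default 1.25 contour
samples). The raw staircase contour overestimates smooth boundaries by
~6% (a rasterized disk of r = 50 px measures ~333 px instead of 2πr ≈
314); with smoothing the disk perimeter is accurate to 0.5% and a 100-px
square to 1%. Larger sigmas keep rounding corners and start to bias
squares; the default balances the two shape families. Pixel-edge counting
is not used at all — it inflates circularity well beyond its upper bound
of 1.

**Area and convex area.** Area is the pixel count × pixel area. Convex
area is the hull of the unsmoothed contour vertices, floored at the
region area so `solidity ≤ 1` structurally.

**Fitted ellipse.** Axes come from the region's second-order central
moments and are then rescaled by a common factor so the ellipse area
π·(major/2)·(minor/2) equals the region area. This convention makes
`roundness × aspect_ratio = 1` an exact identity (verified to 1e-9 on
every measured cell), which is the stated relation between the two
descriptors. Degenerate regions (1-px-wide lines, single pixels) fall
back to area-preserving substitutes.

**Clamping.** Circularity and solidity are clamped to [0, 1]:
discretization can overshoot marginally on near-ideal shapes, and both
quantities are bounded by 1 by definition. Aspect ratio is ≥ 1 by the
major ≥ minor convention.

**Process detection.** The soma is modelled as the maximal inscribed disk
(peak of the Euclidean distance transform). The mask is skeletonized;
connected skeleton branches farther than `soma_margin` (1.1) × soma
radius from the soma centre count as processes if longer than
`min_length_factor` (k = 0.5) × soma radius. The margin keeps boundary
ruffles and the short medial ridge of mildly elongated somata from
counting; k is exposed because no published criterion separates
"processes" from ruffles. An elongated rod contributes up to 2 branches
(its two ends), which is irrelevant to classification because the
aspect-ratio rule takes precedence.

**Classification.** Decision order: 0 processes → round/amoeboid; else
aspect ratio ≥ 3 → polarized/rod-like; else ≥ 3 processes → ramified.
Cells with 1–2 processes and aspect ratio < 3 fall outside the three-class
taxonomy; they are assigned a configurable fallback class (default
round/amoeboid) and flagged, which keeps the binary
[round/amoeboid] vs [polarized + ramified] grouping conservative. Cells
touching the raster border are excluded by default (truncated geometry
corrupts every descriptor).

## Nuclei counting

Gaussian smoothing (2 µm) → global Otsu threshold → hole filling →
optional watershed with markers at distance-transform peaks (minimum peak
separation 5 µm) → area filter (12–600 µm²). The chain is the canonical
one for nuclear stains; all parameters live in `CountConfig` and the
operation is deterministic given raster + config. A blank raster counts 0
without error. Widening the area filter can only add regions, so counts
are monotone in the filter — a property the tests check. Per-cell nucleus
assignment looks up the label under each centroid; centroids over
background are logged and dropped; any cell with ≥ 2 nuclei flags the ROI
as containing multinucleated cells.

## Cytokine calibration

**Model.** `y = D + (A − D)/(1 + (x/C)^B)^g` with lower/upper asymptotes
A, D (response units), inflection-scale C (pg/mL), slope B and asymmetry
g > 0. This is the most common immunoassay parameterization; g = 1
recovers the symmetric 4PL (checked: a 5PL fit of 4PL data reproduces the
4PL curve to <0.1%).

**Fitting.** Trust-region least squares over (A, D, log C, B, log g) with
three log-spaced C starts spanning the standard range, data-driven A/D
starts and the best-SSE solution kept; bounds keep C and g in numerically
sane ranges. Unweighted by default (no weighting is part of the
procedure's definition here); 1/y² relative weighting is available. On
noiseless 6 × 2-point standards the fit recovers all five parameters to
~1e-13 relative. Constant responses or <4 distinct positive levels raise
a calibration error naming the analyte.

**Inversion.** Closed form
`x = C·(((A−D)/(y−D))^(1/g) − 1)^(1/B)`. Responses at or beyond the
fitted asymptotes cannot be inverted and are censored with
`censored_low`/`censored_high` flags — never extrapolated. Within the
assay working range (x within 10^±0.8 of C) the forward/inverse round
trip is exact to ~1e-14 relative; approaching the asymptotes, floating-
point cancellation dominates any implementation.

**Correction chain.** Interpolated concentrations are doubled (the 1:2
sample dilution), the mean concentration of the two medium-only
background wells is subtracted, and negatives are floored at 0
(concentrations are physical). Each treatment well is then expressed as
n-fold of the mean of that animal's two pooled untreated control wells. A
zero control mean yields a missing value with reason code
`zero_control_mean` — the source procedure acknowledges zero-concentration
control wells without defining a divisor fix, so none is invented.

## Trimming and composite Z scores

Outliers are trimmed per (genotype × treatment × metric) group from raw
values with quartile fences Q1 − m·IQR / Q3 + m·IQR, m = 1.7 by default
(wider than Tukey's 1.5; kept as stated but configurable). Quartiles use
linear interpolation between order statistics — the default of the
mainstream stats stacks — and the convention is recorded in output
metadata because the fences depend on it. Fewer than 4 values skip the
rule with a warning.

Z tests score knockout animals against the control genotype:
`z = (X − µ)/σ` with µ, σ the CTRL group's mean and sample SD (ddof 1) of
the same metric and condition; σ = 0 propagates as missing. Cluster
scores are the equal-weight mean over non-missing members (members are
configurable; defaults: core pro = {IL-1b, IL-6, TNFa}, core anti =
{IL-4, IL-10}, "all" pro = the seven non-anti analytes, "all" anti =
{IL-4, IL-10, IL-27}). Combined scores pair each core cytokine cluster
with the directionally matched shape descriptor —
`ProIF = (pro-core z + roundness z)/2`,
`AntiIF = (anti-core z + aspect-ratio z)/2` — and are missing if either
component is missing (no silent imputation).

## Inference

Welch's t (Satterthwaite df, two-sided) for two-group comparisons of
cytokine n-folds; Pearson χ² without continuity correction on the 2 × 2
[round/amoeboid vs polarized+ramified] × [control vs treatment] table
(cell counts in this design are in the hundreds to thousands, where the
Yates correction is negligible); Kruskal–Wallis with tie-corrected H
followed by Dunn's z tests on midranks with Bonferroni adjustment over
the tested pairs (the adjustment method is recorded in the output, since
post-hoc conventions differ between software families); one-way ANOVA
with Tukey's HSD for Z-score panels. Significance tiers: * <0.05,
** <0.01, *** <0.001, **** <0.0001. Under the null, each test's empirical
type-I error at α = 0.05 measures 0.049–0.055 over 2000 simulations.

## Synthetic-data generator

The generator's defaults define the simulated study conditions; they are
stated here once and not tuned per analysis.

**Cell shapes.** Soma = noisy ellipse (radial Fourier perturbation,
relative amplitude `boundary_noise`); processes = tapered protrusions of
decreasing width stamped along slightly curved paths at angularly
separated positions. Construction forces each class's defining feature:
round cells have 0 processes and elongation < 1.6; polarized cells have
elongation ≥ 3.3 (aspect ratio ≥ 3 by construction) and no drawn
processes; ramified cells carry 3–6 processes of 20–32 µm. Per-class size
priors (soma radius 9–14 / 7–10 / 6.5–9 µm) are artifact choices — no
per-morphotype size distributions exist to copy — and sit in the range of
cultured murine microglia somata. On 1000 default-noise cells the
automated classifier recovers the generated class 100% of the time, and
the process detector recovers a 5-process cell as 5 ± 1.

**ROIs.** Default 1000 × 1000 px at 1 µm/px (~1 mm², the sampling unit of
the motivating workflow), non-overlapping placement with a 1-px gap and
bounded retries, one nucleus blob per cell at the soma centre; by default
5% of ROIs contain one binucleated cell. Label ids are contiguous from 1
and the truth table matches the raster exactly.

**Plates.** Per analyte, fixed "true" 5PL parameters (A 25–43,
D 24 000–29 400, C log-spread 120–1270 pg/mL, B ≈ 1, g 0.85–1.3) and a
baseline secretion of 6–50 pg/mL. A sample well contains
(secreted + medium background)/2; background wells contain medium only
(2 pg/mL); responses follow the forward 5PL with multiplicative lognormal
noise (`noise_cv`, default 0.08 — a typical bead-assay replicate CV).
Between-animal baseline spread is lognormal with CV 0.25 and the realized
effect multiplier carries a per-animal lognormal jitter of CV 0.10. At
zero noise the whole plate is exactly invertible by the calibration chain
(corrected concentration = secreted concentration to ~1e-13).

**Effect table.** The per analyte × genotype × treatment fold multipliers
encode the qualitative directions of the study system — stimulation
raises pro-inflammatory cytokines far more in receptor-proficient (CTRL)
than knockout (KO) cultures (e.g. TNFα 25× vs 8× under LPS+BzATP), BzATP
depresses IL-4 in both (1/9 vs 1/6), antagonists lower pro-inflammatory
levels in both and double IL-4 in CTRL only. Magnitudes are free
parameters, not claims about the real system.

**Parametric experiment layer.** For repeated whole-experiment
simulations, per-cell morphotypes are drawn from genotype × treatment
mixtures (round fraction 0.79/0.83 at baseline for CTRL/KO, rising to
0.90–0.93 under stimulation, dropping to 0.67 under antagonists in CTRL
only) with a per-animal logit shift (SD 0.15) shared across conditions,
and descriptor values from the class-conditional distributions the
renderer targets (roundness ~ N(0.82, 0.07) / N(0.26, 0.05) /
N(0.45, 0.08) for round/polarized/ramified, clipped; aspect ratio its
reciprocal; lognormal areas around 380–520 µm²). This layer exists so
that 100-replicate direction checks finish in minutes; the rendered-image
layer feeds the same downstream code in the default pipeline.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: optics (PSF, shading, z-projection artifacts),
segmentation error (masks are ground truth by construction), touching or
overlapping cells, staining variability, bead-count-dependent assay
noise, matrix effects beyond a constant medium background, and any
real-animal effect magnitudes. Tests demonstrate that the computational
pathway is correct and recovers programmed structure, not that the
motivating study's numbers are reproduced.

## Problem sizes and determinism

Every generator is a pure function of (parameters, seed); the pipeline
derives all stage seeds from one root seed and reproduces its output
tables byte-for-byte. Default simulation sizes were chosen so the full
test suite and the acceptance script each complete in a few minutes on a
single core: 1000 rendered cells for recovery/reciprocity checks, 2000
null replicates per test for type-I calibration, 100 repeated experiments
with 8 animals per genotype arm and 300 cells per animal × condition for
the direction checks, 200 nuclei for counting accuracy. The default
`RunConfig` for the demo pipeline uses 3 animals per genotype, 2 ROIs of
384 × 384 px and 15 cells per ROI.

## Known limitations

* The process detector is one reasonable operator for an undefined manual
  criterion; its k threshold changes absolute process counts (not the
  classification of clearly round or clearly ramified cells).
* Censored concentrations propagate as missing values; no imputation or
  Tobit-style modelling is attempted.
* Wells within an animal are pooled, not modelled hierarchically; a
  mixed-effects treatment of well-within-animal nesting is out of scope.
* The χ² routing assumes independent cells; within-ROI correlation is
  ignored, as in the motivating analysis.
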