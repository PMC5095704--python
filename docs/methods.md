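# Methods

This note documents the models, conventions and numerical choices behind
`bfmap`, and what its synthetic benchmarks do and do not demonstrate.

## Coordinate conventions

In-plane pixel coordinates are 0-based, written `(x, y)` = (column, row):
`x` increases laterally (mediolateral axis), `y` increases ventrally
(dorsoventral axis). Atlas in-plane coordinates are expressed in atlas
pixels, with the pixel size in µm carried on the label field.
Anterior–posterior (AP) positions are in mm relative to bregma, positive
anterior. Hemisphere laterality is an explicit per-cell flag (`ipsi` /
`contra`) rather than being inferred from atlas geometry.

## Region ontology

The ontology is a validated tree: one root, unique integer ids, levels
recomputed from the parent chain (declared levels are checked, not
trusted). Level 1 holds the major brain subdivisions (12 in the mouse-brain
convention used throughout); a flagged subset of deeper nodes are the named
analysis areas (53 by default). Counts landing in unnamed descendants of a
subdivision accumulate in a synthetic `"<subdivision>-other"` bucket, since
named-area counts need not sum to the subdivision total. This guarantees
the conservation property: fractions at any level sum to 1, and rolling
finer levels up reproduces coarser ones to machine precision.

## Registration model

The section-to-atlas map is `p_atlas = S · R(θ) · p_image + t`,
`S = diag(s_ml, s_dv)`, both scales strictly positive (reflections are
disallowed; flipped sections must be pre-flipped). Rotation is applied
first, then anisotropic scaling in the atlas axis frame, then translation —
the composition order is a package choice that makes the five parameters
identifiable; only the independence of the two axis scales is dictated by
the tissue-compression rationale.

Fitting minimizes the sum of squared atlas-frame residuals. A closed-form
similarity (Umeyama) fit initializes θ, a common scale and t; Gauss–Newton
then refines all five parameters with an analytic Jacobian, converging when
the step's infinity norm drops below 1e-10 or after 100 iterations. From
the similarity start this converges on all tested configurations (scales
0.7–1.3, |θ| ≤ 25°). Degenerate inputs — fewer than 3 pairs, or collinear
image points (centered point matrix numerically rank-deficient) — raise a
dedicated error. The reported RMS is `sqrt(mean_i ||r_i||²)` over pairs;
with isotropic landmark noise σ and n pairs its expectation is
`σ·sqrt(2(1 − 5/(2n)))` (2n residual components, 5 parameters), which the
tests verify empirically. The anisotropic fit's RMS is never above the
similarity-constrained fit's on the same landmarks.

Image resampling (inverse mapping, bilinear interpolation, out-of-field
pixels 0) exists for visual inspection only: detection runs on raw images
and detected coordinates are transformed as points, so quantification never
depends on resampling artifacts.

## Ridge detection

Per scale σ (defaults {1, 2, 4} px, covering widths ~1–8 px via σ ≈
width/2): Gaussian-derivative Hessian; eigenvalue of largest magnitude with
negative sign (bright ridges); response `−λ·σ²` (scale-normalized);
threshold `ridge_strength_min` (absolute, default 10 intensity units,
sized against the synthetic amplitude of 100); non-maximum suppression
along the corresponding eigenvector with bilinearly interpolated
neighbors. The per-scale maps are unioned and thinned to a 1-px skeleton.

The background mask keeps pixels strictly above the `mask_percentile`-th
percentile of the raw image (default 90; a `mean + k·std` alternative is
provided since the original thresholding rule is distribution-based but
otherwise unspecified). Connected components below `min_component_size`
(default 20 px) under 8-connectivity (4 available) are removed. The
"repeat until satisfactory" refinement is realized as an explicit parameter
schedule so runs are reproducible, and the iteration log records surviving
pixel counts per pass; a manual reject mask is applied as a final set
difference with relabeling. Identical image and parameters give
bit-identical results.

Choosing the Hessian-eigenvalue realization (rather than an off-the-shelf
vesselness filter) keeps the defining property explicit and testable:
skeleton pixel count is proportional to centerline length (R² ≥ 0.98 over
lengths 50–400 px) and insensitive to width (max/min count ratio ≤ 1.2
over widths 1–7 px).

## Quantification rules

- **Exclusion zone:** input cells are removed when their *section* lies
  within 850 µm AP distance of the injection site (strictly-greater-than
  850 µm is kept; ties are excluded), matching a per-section reading of the
  rule; and anywhere in the brain when assigned to a configured excluded
  region (the diagonal-band analog by default). Starter cells are never
  removed. Distances are compared in mm to avoid unit-conversion rounding.
- **QC:** a brain is excluded when fewer than 200 input cells remain
  (strict `<`; exactly 200 is kept).
- **Normalization:** per-region counts divided by the per-brain included
  total. Both hemispheres enter the denominator; the contralateral share is
  reported separately, since published per-region percentages do not state
  denominator handling. Fractions are computed on imaged sections only,
  with no volumetric correction.
- **Axon outputs:** each cleaned-ridge pixel is mapped as a point and
  assigned by nearest-pixel label lookup; pixels in the configured
  injection-site/fiber-tract region list or outside the brain contribute
  nothing and are logged.
- **Starters** feed only the convergence index (inputs per starter,
  undefined without starters) and the density maps.

## Comparison statistics

CCs are plain Pearson coefficients, by default at the 12-subdivision level
(finer levels via config; `-other` buckets participate, with a config flag
to drop them). Cell-type matrices use arithmetic means of per-sample
fractions; input/input and output/output matrices are symmetric with unit
diagonal, input/output matrices are asymmetric and orientation is explicit.
For within/across analysis all unordered sample pairs are pooled once each,
self-pairs (CC = 1 by construction) excluded, and the two groups compared
with Welch's unequal-variance t-test — the unequal group sizes and
variances make the pooled-variance variant less defensible, and the
original analysis does not specify. Groups with fewer than two pairs, or
all-identical samples, skip the test with a warning. A one-way ANOVA per
region across cell types is included as a descriptive convenience only
(no multiple-testing machinery).

## Starter density maps

Starter cells join the AP slab whose half-open interval
`[center − 0.12, center + 0.12)` mm contains them (0.24 mm slabs; a cell
exactly midway goes to the more anterior bin; no cell is double-counted).
Per-slab 2D histograms on the atlas grid are pooled over samples of a cell
type, optionally Gaussian-smoothed with reflective boundaries (mass-
conserving; bandwidth default 2 atlas px, 0 allowed), and scaled so the
maximum over all slabs is exactly 1. Pooling-then-normalizing is the
default; normalizing each sample before averaging is a config alternative,
as the published normalization is not fully specified. Bicubic upsampling
maps output node `m` to input coordinate `m/factor`, so original lattice
points are reproduced exactly (cubic-spline interpolation is exact at
knots); negative overshoot is clipped to 0.

## Synthetic data: what it emulates, and what it does not

The generator supplies every input the pipeline consumes, reproducibly from
one root seed fanned out to per-stage child seeds.

- **Atlas:** block-structured label grids — subdivisions as vertical
  strips, named areas as horizontal bands plus one unnamed remainder band
  per subdivision (exercising `-other` accounting); sections share one
  in-plane grid, AP-spaced at 0.09 mm (every third 30 µm section imaged).
- **Sections:** axons as unit-step random-heading polylines (heading noise
  0.06 rad/px) that bounce off their region's boundary, rendered with a
  Gaussian cross-section (FWHM = nominal width, 1–5 px default, peak
  amplitude 100) over constant background 20, Gaussian noise at SNR 5
  (amplitude/σ) and 0.1% bright speckle. Ground truth records every
  centerline, width, and per-region pixel tally.
- **Cells:** per sample, a Dirichlet-perturbed copy of its cell type's
  area profile (inverse concentration 1/300) and multinomial placement at
  random pixels of the drawn area, in sections strictly outside the
  exclusion zone; 300 contamination cells planted inside the zone;
  starters at the injection target; contralateral probability 0.03 (inside
  the reported "<5% contralateral"). Whole-brain counts are drawn from the
  reported 900–14,631 range, with 5/5/3/4 samples for ChAT/VGLUT2/PV/SOM.
  The default type profiles are qualitative — striatum and hypothalamus
  heaviest, medulla/cerebellum near zero, with type-specific emphases large
  relative to the within-type perturbation so within-type variability is
  smaller than across-type differences *by construction*. No claim is made
  of reproducing the original per-region percentages.
- **Landmarks:** non-collinear image points pushed through a known
  transform, plus optional isotropic noise.

Passing tests on these data demonstrate correctness of the computations
(registration inversion, centerline recovery, exclusion bookkeeping,
normalization conservation, CC structure recovery) — not performance on
real histology, which adds uneven illumination, autofluorescence,
section damage and registration model violations that the generator
deliberately omits (no PSF or photorealistic noise model).

## Problem sizes and defaults

Default pipeline scale is chosen for quick, single-CPU runs: 160×224 atlas
sections (25 µm pixels, 40 sections), 256×256 detection benchmarks, 6
axons per imaged section, 3 output samples per type with 6 imaged sections
each. A full default run completes in well under a minute and is
byte-reproducible: rerunning an unchanged (config, seed) rewrites identical
files, and the manifest checksums every output.

## Known limitations

- All simulated brains share one atlas geometry and one set of per-section
  true transforms; real cohorts have per-brain sectioning geometry.
- The exclusion rule is per-section (whole coronal sections dropped), the
  stricter of the two readings of the published rule.
- Axon region assignment maps ridge pixels as points; partial-volume
  effects at region borders are resolved by nearest-pixel lookup.
- Overlapping axons merge in the ridge image (pixel counts, not axon
  counts, are the quantified unit), and unique-pixel tallies saturate at
  extreme axon densities.
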