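# Methods

This note documents the models, parameter choices and numerical decisions
behind `cushionmorph`, in the spirit of a methods appendix: what each
computation assumes, which knobs matter, and what the synthetic-data tests
do and do not demonstrate about real data.

## Band tightness

The constriction induced by outflow-tract banding is quantified as
`1 − Da/Db` on the maximum external diameters of the post- and pre-banding
diameter traces. The maximum is taken over the whole trace rather than per
cardiac cycle: the quantity is defined on maxima, traces span only ~3–4
cycles, and cycle segmentation would add machinery without changing the
result. An optional running-median filter (odd window, default off) guards
against single-frame segmentation spikes. Negative values (apparent
dilation) are returned and flagged rather than raised, since sham traces
with measurement noise can straddle zero.

The 30–45% selection window used for the electron-microscopy and
proteomics arms is implemented as a closed interval with configurable
endpoints, because "between 30 and 45%" does not specify endpoint
handling; the choice is recorded here and visible in the API defaults.

The trace generator produces a raised-cosine pulsatile waveform with a
systolic peak exactly on frame 0, so the noise-free maximum equals the
nominal baseline and seeded tightness is recovered exactly at zero noise.
Defaults mirror the acquisition protocol: 200 frames at 140 fps, ~3.3
cardiac cycles (2.3 Hz), 700 µm baseline maximum, 25% peak-to-peak
pulsatility, 2 µm additive Gaussian noise. The waveform is strictly
periodic; real traces drift in rate and baseline, so recovery accuracy on
synthetic traces is an upper bound.

## Confocal cushion quantification

All geometry runs through "rays": segments from points sampled at equal
arc length along the lumen-edge polyline to the nearest point of the
myocardium-edge polyline. The ray length is the local cushion width. This
operationalizes "across the whole width of the cushion from the lumen
edge" without assuming any global cushion shape.

* **Intensity profiles** sample each ray bilinearly and average per
  normalized-position bin (default 50 rays × 20 bins × 4 samples/bin).
  Position 0 is the lumen edge. The innermost-25% mean is the mean of
  bins with position ≤ 0.25; with equal-width bins, the fraction-1 mean
  equals the full-profile mean by construction.
* **Sub-endocardial cell density** counts supplied nuclei centroids inside
  the pixel region that is (a) between the two polylines and (b) within
  10 µm of the lumen edge, and divides by the region's pixel area
  (reported per 1000 µm²). Nuclei are consumed as centroids — from the
  generator or an external segmentation — not detected internally, since
  the original workflow outlined nuclei manually and a blob detector would
  be separately validated scope.
* **Per-length counts** (cells, VE-cadherin junctions) count points within
  a capture distance (default 5 µm) of the lumen-edge polyline, per
  100 µm of its arc length. The inclusion rule is centroid-to-polyline
  distance; the capture default covers an endocardial cell's half-width.
* **Periostin front** scans each ray from the myocardium end toward the
  lumen on the Gaussian-smoothed channel (default σ = 2 µm) and takes the
  farthest point from the myocardium whose intensity reaches the
  threshold — half of that ray's maximum by default, with an absolute
  mode available. Per-ray percentages of width are averaged. Half-max
  makes the measure invariant under global intensity rescaling; rays whose
  maximum falls below a configurable noise floor are excluded.

Per-embryo aggregation is the unweighted mean over slices and cushions,
with inner/outer sub-means retained for the cushion-symmetry comparison.

The slice generator renders two mirrored cushions with straight myocardium
edges and a sinusoidally bulging lumen edge, so the true local width at
any lumen-edge point is available in closed form. Jelly nuclei follow a
spatial Poisson process (default 8 per 1000 µm², a realistic
cardiac-jelly nuclear density at this developmental stage); endocardial
nuclei sit every 10 µm along the lumen edge, nudged 1.5 µm into the
tissue; junction puncta appear between a stated fraction of adjacent
endocardial nuclei; the periostin channel is a step at the stated front
fraction. All channels get a Gaussian point-spread blur (σ = 1 µm) and
additive Gaussian noise (σ = 2 intensity units). The generator does not
emulate depth-dependent attenuation, anisotropic PSFs, staining
variability, or curved myocardium edges, so passing recovery tests bound
geometric and counting errors of the estimators — not robustness to
real-stain artifacts. Density recovery on single slices is limited by
Poisson counting error in the ~2900 µm² band (~20% per slice) and only
the multi-slice average is held to the 5% recovery tolerance.

## 3D cell morphometry

Descriptors are computed in world coordinates (voxel index × spacing, µm),
so anisotropic acquisitions (e.g. 10 nm milling steps) need no special
handling.

* **Volume** is voxel count × voxel volume.
* **Surface area** comes from a spacing-aware marching-cubes isosurface at
  level 0.5 of the binary mask after Gaussian pre-smoothing with σ = 1
  voxel. The smoothing is load-bearing: raw marching cubes on a binary
  mask carries a resolution-independent ≈ +9% area bias on spheres
  (staircase facets), which cubes the error in the shape factor. With
  σ = 1 the voxelized-sphere shape factor converges to 1 within 2% at
  diameters ≥ 40 voxels and monotonically with resolution. The cost is
  shrinkage of features only a few voxels across (≈ −2% area at 8–10
  voxels per semi-axis) and rounding of genuinely sharp corners — a
  10-voxel cube measures ~18% below its exact area. Cells are smooth, so
  the trade favors smoothing; `smoothing=0` restores the raw mesh.
  Masks are padded before isosurfacing, which caps boundary-truncated
  cells with a flat face so their areas remain well defined.
* **Covariance eigenvalues** use voxel centers with uniform weight (solid
  body convention) and subtract Sheppard's grouping correction
  (spacing²/12 per axis), so the eigenvalues estimate the continuous
  solid's covariance: a (4,2,2) µm ellipsoid at 0.25 µm spacing yields an
  elongation factor of 0.255 corrected vs 0.256 raw against the exact
  0.25 (= squared semi-axis ratio of a uniform solid).
* **Inclusion filters**: the SA/V and shape-factor subset keeps cells with
  volume strictly greater than 100 µm³ (excluding overly truncated
  fragments); the elongation subset keeps cells "centered in the image
  volume", operationalized as no voxel on any volume face (configurable
  margin, default 0). The two subsets legitimately differ in size.
* **Group summaries** pool cells across embryos (n counts cells). Folds
  are banded/control for SA/V and shape factor and control/banded for
  elongation ("decreased by a factor of"); the SD fold (banded/control)
  tracks the variance inflation expected when only a subpopulation of
  cells transitions. The default test is the pooled-variance Student
  t-test to mirror the original analysis; Welch is available and is the
  better choice under that variance inflation.

The volume generator places prolate-ellipsoid cell bodies (optionally with
capsule spikes — cylinders with hemispherical caps anchored at random
surface points along the outward normal) at uniform random centers;
first-placed cells win contested voxels, cells reduced below half their
intended volume are resampled, and boundary truncation is allowed on
purpose. Ground truth per cell is brute force on a supersampled grid
(default 8× per axis): fine-voxel counting for volume, fine-voxel moments
for covariance, and a fine isosurface for area, all on the implicit solid
clipped to the volume bounds. For pure ellipsoids the tests additionally
use closed forms (Legendre elliptic-integral surface area, eigenvalues
∝ squared semi-axes) as fully independent oracles. Cell-shape realism is
limited: real transitioning cells are neither rigid ellipsoids nor have
rigid cylindrical filopodia; the generator's role is exact ground truth
for the descriptors, not morphological fidelity.

## TMT proteomics

The pipeline consumes PSM-level tables with ten reporter intensities and
identification metadata, and applies, in order: the identification filter
(q ≤ 0.05 inclusive, |mass error| < 20 ppm strict, unique protein match);
the signal filter (exclude the single highest and lowest reporters — ties
broken toward the lowest channel index — and require the remaining
eight's mean to exceed 500 strictly); replacement of zero reporters by 150
on passing PSMs (applied after the pass/fail decision, matching the
stated order of operations; a flag applies it before); per-protein,
per-channel summation; and channel normalization scaling each channel's
total to the grand mean (the in-silico analogue of pooling samples to
equal summed reporter intensity). The excluded extremes still count in
protein sums: the trimming exists to judge signal sufficiency, not to
censor quantitation — this reading is configurable.

Differential abundance replaces the original edgeR negative-binomial
machinery with a Welch two-sample t-test on log2(normalized + 1) per
protein (pseudo-count 1), Benjamini-Hochberg adjustment across proteins,
and the signed x-fold convention (−2.0 = halved in banded). The
substitution is deliberate and documented: reporter-ion sums are not
counts, the spike-in and FDR simulations validate the Welch route
directly, and edgeR equivalence is not claimed anywhere. Single-PSM
proteins are not treated specially beyond carrying their `psm_count`.

The generator draws protein abundances log-normal (median 5000, σ = 1),
per-PSM peptide factors (σ = 0.5, shared across channels within a PSM),
per-channel loading factors (~10% spread, recoverable by the
normalization step), multiplicative reporter noise at a stated CV
(default 0.2), sparse zero dropouts (1%), and small fractions of
quality-filter failures so every filter is exercised. Spiked proteins get
a ±1 log2 fold change by default. Correlated interference (co-isolation),
isotopic impurity and channel-specific missingness are not modeled.

## Statistics

Pooled-variance Student is the default two-sample test (matching the
original reporting); Welch is one keyword away. Zero-variance degenerate
inputs return p = 1 with a flag when the groups are identical and raise
otherwise. OLS R² is 1 − SS_res/SS_tot via `scipy.stats.linregress`. BH
adjustment is the standard step-up (statsmodels `fdr_bh`); note BH
adjustment is not idempotent in general — re-adjusting adjusted values
can change them — so only bounds and monotonicity are asserted as
invariants. The study report carries imaging-arm significance at α = 0.05
and the proteomics reporting threshold p < 0.1, both configurable, and
emits the per-embryo values needed to recompute every summary.

## Problem sizes and runtime choices

Tests use grids that keep the full suite around a minute and a half:
voxelized spheres up to diameter 50, random-ellipsoid oracle checks at
0.25 µm spacing with 8×-finer brute force, 20 synthetic cushion slices
for confocal recovery, and 20-seed × 500-protein simulations for spike-in
recovery and FDR control. These sizes are chosen so that each tolerance
is dominated by the estimator under test rather than by simulation noise.

## Known limitations

* Absolute surface areas are estimator-relative (smoothing level, mesh
  resolution); ratios, folds and recovered parameters are the validated
  surfaces.
* The confocal arm assumes supplied polyline annotations and centroids;
  no automatic segmentation is provided.
* The elongation "centered in volume" criterion is a proxy (face contact),
  not a statement about how much of the cell was captured.
* Generators are minimal statistical models of the imaging and
  mass-spectrometry processes; they establish correctness of the
  estimators, not robustness to every real-world artifact.
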