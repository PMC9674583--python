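# Methods

`stedtex` quantifies the nanoscale spatial organisation of a fluorescent
signal (the motivating case is hyaluronan stained at the periphery of
migrating fibroblasts, imaged by deconvolved STED microscopy at 25 nm pixel
sampling) and compares that organisation between two groups of cells. The
pipeline has four stages: grid segmentation restricted to an expert-marked
region of interest, per-block patch statistics, per-block rotation/offset-
robust texture features, and nonparametric group inference. A synthetic image
generator with full ground truth makes every stage verifiable without real
microscope data.

## Grid segmentation

Each image is tiled into fixed-size blocks starting at the top-left corner,
with 0-based (row, col) coordinates and half-open pixel bounds so blocks are
pairwise disjoint. The default block is 100 × 100 px (≈ 2.5 µm at 25 nm
pixels). Truncated right/bottom remainder tiles are excluded by default —
patch counts and texture statistics are block-area-dependent, so analysed
blocks should all have identical area — but can be included with
`grid.include_truncated_edge_blocks`. A block enters the analysis if at least
one ROI-foreground pixel falls inside its bounds ("partially or wholly
overlapped"); block selection is therefore monotone in the ROI. Intensities
are analysed raw: no normalisation is applied within or across images.

## Patch statistics

Each selected block is binarised at an Otsu threshold computed *per block*:
the threshold maximises the between-class variance w₀w₁(µ₀ − µ₁)², evaluated
exactly over the block's observed intensity levels rather than over a coarse
histogram. Candidate thresholds are the midpoints between consecutive
observed levels; ties within floating-point round-off of the maximum take the
lowest candidate, and foreground is strictly-greater-than the threshold. A
constant block has no separable classes and is flagged degenerate: its patch
statistics are undefined (empty CSV fields), but its texture features are
still computed (a constant block has a well-defined GLCM), so block counts
stay comparable across features.

Foreground pixels are grouped by 8-connected component labelling; each
component is a "patch" (interpreted as one nanoscale cluster). Per block the
pipeline reports the patch count, the mean patch area in pixels, and two
intensity readouts that are deliberately kept separate:

- `mean_fg_intensity` — mean original intensity over all foreground pixels
  (pixel-weighted; large patches dominate);
- `mean_intensity_per_patch` — unweighted mean over patches of each patch's
  mean intensity.

They answer different questions ("how bright is the signal-containing area"
vs "how densely packed is a typical cluster") and diverge whenever patch
size and brightness covary. No minimum patch size is imposed by default
(`min_patch_area_px = 1`; single-pixel components count).

## Texture features

For each block a gray-level co-occurrence matrix (GLCM) is accumulated at 12
spatial offsets — (dx, dy) displacements of 1–4 px along 0°, 45° and 90° —
after linear quantization to `glcm.levels` gray levels (default 64) over the
block's own min–max range. 64 levels balances histogram occupancy of a
10⁴-pixel block against discretization artefacts; the level count and a
global-range quantization mode are configurable. GLCMs are symmetric
(each pair counted in both orders) and normalised to sum 1. Per GLCM three
Haralick features are computed:

- Energy = Σᵢⱼ p(i,j)²  (local uniformity; 1 for a constant block)
- Contrast = Σᵢⱼ (i−j)² p(i,j)  (weight on large local intensity jumps)
- Homogeneity = Σᵢⱼ p(i,j)/(1+(i−j)²)  (closeness of the GLCM to diagonal;
  the inverse-difference-moment form; 1/(1+|i−j|) is a config switch)

The 12 values of each feature form a 4 (distance) × 3 (angle) matrix, reduced
to a single scalar by its leading singular value scaled by 1/√12. A
non-square matrix has no eigenvalues, so the leading singular value is the
natural "first eigenvalue" reduction; the 1/√12 scaling makes a constant
matrix of value c map to exactly c, so the constant-block limits (energy 1,
contrast 0, homogeneity 1) survive the reduction. Singular values are
invariant under column permutations, which is what makes the reduction
rotation-robust. Heterogeneity = 1 − homogeneity (invariant form).

**Exactness of the rotation invariance.** A quarter turn permutes the angle
families 0° ↔ 90° but maps the 45° diagonal family (k, k) onto the 135°
family (k, −k), which is *not* in the offset set. The invariance is therefore
exact (to float round-off) for 180° rotations of any block (symmetric GLCMs
make (dx,dy) ≡ (−dx,−dy)), and for 90°/270° rotations of blocks whose mirror
symmetry makes the 45° and 135° co-occurrence statistics coincide. For
generic blocks a quarter turn changes only the diagonal column, so the
descriptor is rotation-*robust* rather than strictly invariant; the tests
assert the exact cases.

## Group statistics

All selected blocks of a group's images are pooled into one sample per
feature (the literal block-level reading; per-image averaging is available
via `stats.pooling = "image"` because block pooling ignores within-image
correlation — a known limitation, see below). Per feature:

- **Mann–Whitney U** (two-sided), U = #{xᵢ > yⱼ} + ½#{xᵢ = yⱼ}: exact
  enumeration p-value when the pooled sample is tie-free and n·m ≤ 400,
  otherwise normal approximation with tie-corrected variance and continuity
  correction. If all values are identical the statistic is n·m/2 and p = 1
  (the asymptotic variance vanishes).
- **Bootstrap difference of medians**: x and y resampled independently with
  replacement (default `n_boot` = 10 000), percentile 95% CI of the bootstrap
  difference distribution around the observed median(x) − median(y). The
  percentile interval is the simplest estimator consistent with the design;
  BCa was considered and left out to keep the CI definition transparent.
- **SE of the median** as the SD (ddof = 1) of bootstrap medians — the
  estimator is otherwise unspecified by convention, and the bootstrap is
  assumption-free; **notched box statistics** use notches at
  median ± 2·SE(median) and linear-interpolation quartiles
  (`numpy.percentile` default).

Undefined entries (patch means of zero-patch blocks) are dropped per feature
with the per-feature n reported. Seven features are compared by default
(patch_count, mean_patch_area_px, mean_fg_intensity, mean_intensity_per_patch,
energy, contrast, heterogeneity); homogeneity is stored but not tested, being
the exact complement of heterogeneity. No multiple-testing correction is
applied by default; Bonferroni and Benjamini–Hochberg are config options.
All bootstrap seeds derive per feature from the master seed, so results are
bit-reproducible.

## Synthetic data generator

The generator emulates the imaging regime, not the optics: a constant
background (default 10 counts) plus isotropic Gaussian spots (σ =
`radius_px`) at centres drawn from a homogeneous spatial Poisson process
restricted to a lamellipodium-like ROI (an axis-aligned band covering the
bottom 30% of the image by default, or a half-ellipse "polygon" variant),
with lognormal per-cluster radii and peak intensities and optional per-pixel
Poisson shot noise. The expected cluster count is `count_per_block` per
100 × 100 px of ROI area. Images are written as 16-bit unsigned TIFF, masks
as 8-bit 0/255 TIFF, and every placed cluster (subpixel centre, σ, peak) is
recorded as ground truth JSON.

Preset regimes (defaults, 512 × 512 px at 25 nm):

| parameter | control | invasive |
|---|---|---|
| count_per_block | 8 | 16 (×2) |
| radius_px (σ) | 2.0 (50 nm) | 3.0 (×1.5) |
| peak_intensity | 120 | 84 (×0.7) |
| radius_cv / intensity_cv | 0.25 / 0.3 | same |

The invasive preset mirrors the direction of the phenotype the pipeline is
meant to detect — more clusters per surface area, ~50% larger clusters, lower
per-cluster pixel intensity — with magnitudes chosen as plausible
conventions (no quantitative ground truth for real cluster densities is
available to calibrate against). Homogeneous Poisson placement is a neutral
null: all group structure is carried by count, size and intensity, exactly
the quantities the pipeline measures.

What the generator does *not* emulate: STED depletion/deconvolution
artefacts, spatially varying background, cluster–cluster attraction or
exclusion, ROI shape irregularity, and image-to-image staining variability.
Passing tests on synthetic data therefore demonstrate that the measurement
chain recovers known inputs and that the statistics are calibrated — not
that real cell groups differ.

## Numerical and design choices

- Exact per-block Otsu (observed-level midpoints) instead of a binned
  histogram: deterministic, tie-stable, and verifiable against an exhaustive
  scan; on 10⁴-pixel blocks the cost is negligible.
- GLCMs accumulated directly from integer (dx, dy) displacements with numpy;
  the distance-angle parametrisation of common library routines cannot
  express diagonal displacement (k, k) unambiguously (its Euclidean length
  k√2 is not an integer pixel distance).
- Quantization maps the block maximum into the top level (values binned by
  floor(L·(v−min)/(max−min)) then clipped to L−1).
- Degenerate inputs: constant blocks → patch stats undefined, texture
  defined; empty masks, shape mismatches, unknown groups, zero selected
  blocks → hard errors naming the offending file (fail-fast; silent skips
  would change the statistical sample).
- Per-image generator seeds and per-feature bootstrap seeds derive from the
  master seed via `numpy.random.SeedSequence.spawn`, keeping every derived
  seed below 2³¹ and the whole simulate → extract → compare chain
  byte-reproducible.
- Problem sizes in the tests and the acceptance script (512 × 512 preset
  images, 3–4 images per group ≈ 30–40 blocks per group, 500 calibration
  replicates with 2 000 bootstrap resamples) are the package's default
  desk-scale study: large enough that every directional effect is detected at
  p < 0.01 and coverage is estimated to ±1%, small enough to run in seconds.

## Known limitations

- Block-level pooling treats blocks from the same cell as independent;
  within-image correlation inflates effective sample size. Image-level
  pooling is provided but reduces power at small image counts. A hierarchical
  model is out of scope.
- The invariant form is strictly rotation-invariant only under the conditions
  stated above, because the offset set lacks the 135° family.
- Otsu binarisation of a noisy block with no real signal segments the noise;
  patch counts in signal-free blocks are therefore noise-dependent. The
  degenerate flag only covers exactly-constant blocks.
- Merged clusters are counted as one patch (no watershed splitting), so patch
  counts saturate at high cluster densities.
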