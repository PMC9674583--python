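# stedtex

Block-wise quantification of nanoscale signal organisation in
super-resolution fluorescence images, and nonparametric comparison of that
organisation between two groups of cells.

The motivating problem: hyaluronan — an extracellular-matrix
glycosaminoglycan — assembles into sub-diffraction clusters at the leading
edge of migrating fibroblasts, visible in deconvolved STED images sampled at
~25 nm/pixel. Whether an invasive phenotype reorganises those clusters (more
of them? larger? dimmer?) is a question about spatial statistics, not about
total signal. `stedtex` answers it with a pipeline aimed at anyone comparing
punctate super-resolution signal between conditions:

1. **Segmentation** — each image is tiled into a grid of 100 × 100 px blocks
   from the top-left corner; every block partially or wholly overlapped by an
   expert-marked ROI (e.g. the lamellipodium) is analysed, on raw
   intensities.
2. **Patch analysis** — each block is binarised at an exact per-block Otsu
   threshold (maximising between-class variance w₀w₁(µ₀−µ₁)²) and segmented
   into 8-connected foreground components ("patches" = clusters), giving
   patch count, mean patch area, mean foreground intensity, and mean
   per-patch intensity.
3. **Texture** — per block, gray-level co-occurrence matrices at 12 offsets
   (distances 1–4 px at 0°, 45°, 90°) yield Haralick Energy Σp², Contrast
   Σ(i−j)²p and Homogeneity Σp/(1+(i−j)²); each feature's 4 × 3
   distance-by-angle matrix is reduced to a rotation/offset-robust scalar by
   its leading singular value (scaled 1/√12), and Heterogeneity = 1 −
   Homogeneity.
4. **Group statistics** — per feature, blocks are pooled within group and
   compared with a two-sided Mann–Whitney U test plus a bootstrap
   difference-of-medians with percentile 95% CI; notched-box statistics use
   median ± 2·SE(median) (bootstrap SE).

A synthetic STED-like image generator (Gaussian clusters placed by a spatial
Poisson process inside a lamellipodium-like ROI, with ground truth and
Poisson shot noise) makes the whole chain testable end to end; see
`docs/methods.md` for the model, parameter defaults and limitations.

## Worked example

Simulate a two-group dataset (3 images per group; "invasive" preset = twice
the cluster density, 1.5× the radius, 0.7× the peak intensity of "control"),
extract per-block features, and compare the groups — all from one seed:

```sh
stedtex all --out run --seed 11 --n-per-group 3
```

prints (diff = median(control) − median(invasive)):

```
patch_count: diff=-5 p=0.000181
mean_patch_area_px: diff=-26.26 p=6.01e-08
mean_fg_intensity: diff=14.96 p=4.08e-05
mean_intensity_per_patch: diff=18.82 p=9.06e-08
energy: diff=0.02619 p=0.000318
contrast: diff=-7.478 p=0.000225
heterogeneity: diff=-0.09024 p=0.000301
```

Read: invasive-like images carry ~5 more patches per block whose median area
is ~26 px² larger, with higher contrast and heterogeneity and lower energy
(the signal is rougher and less uniform), while per-patch intensity is lower
— every shift significant well below p < 0.01 with 30 blocks per group.
`run/` now holds the images, masks, ground truth, `features.csv` (one row per
selected block), and `comparison.json`/`comparison.csv` (per-feature U, p,
medians, bootstrap CI, notch bounds, with the full config echoed for
provenance). Add `--plots` for notched box plots with the median drawn as a
thin red line.

The same stages run separately on real data: `stedtex extract --labels
labels.csv --out features.csv` with a CSV of `image_path,mask_path,group`
rows (single-channel TIFF/PNG images and binary masks), then `stedtex
compare`. Defaults live in a YAML config
(`grid.block_size_px`, `glcm.levels`, `stats.n_boot`, `stats.seed`, …);
library functions mirror every subcommand (`stedtex.generate_group_dataset`,
`run_extract`, `compare_groups`).

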