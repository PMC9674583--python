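"""Per-block patch statistics: Otsu binarization and 8-connected components.

Each selected grid block is binarized with a threshold that maximizes the
between-class intensity variance (Otsu's criterion, computed exactly over the
block's observed intensity levels rather than over a coarse histogram), then
analysed with 8-connected component labelling. Connected foreground
components are the "patches" (nanoscale clusters); their count, mean area and
two intensity readouts are the per-block statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

#: 8-connectivity structuring element (diagonal neighbours touch).
_STRUCTURE_8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class PatchStats:
    """Patch statistics of one block; means are NaN when patch_count = 0.

    mean_fg_intensity is the mean original intensity over *all* foreground
    pixels (pixel-weighted); mean_intensity_per_patch is the unweighted mean
    over patches of each patch's mean intensity. The two differ whenever
    patch areas and brightnesses covary.
    """

    patch_count: int
    mean_patch_area_px: float
    mean_fg_intensity: float
    mean_intensity_per_patch: float
    otsu_threshold: float

    def __post_init__(self) -> None:
        undefined = [math.isnan(v) for v in (
            self.mean_patch_area_px, self.mean_fg_intensity, self.mean_intensity_per_patch)]
        if self.patch_count == 0 and not all(undefined):
            raise ValueError("patch_count = 0 requires all mean fields undefined")
        if self.patch_count > 0:
            if any(undefined):
                raise ValueError("patch_count > 0 requires all mean fields defined")
            if self.mean_patch_area_px < 1:
                raise ValueError("mean_patch_area_px must be >= 1 when patches exist")


def otsu_threshold(block_pixels: np.ndarray) -> float:
    """Exact Otsu threshold of a block, or NaN for a degenerate block.

    Candidate thresholds are the midpoints between consecutive observed
    intensity levels; the returned value maximizes the between-class variance
    w0*w1*(mu0 - mu1)^2 with foreground = pixels strictly greater than the
    threshold. Ties take the lowest candidate. A constant block has no
    separable classes and returns NaN.
    """
    v = np.asarray(block_pixels, dtype=np.float64).ravel()
    if v.size == 0:
        raise ValueError("empty block")
    levels, counts = np.unique(v, return_counts=True)
    if levels.size < 2:
        return float("nan")
    n = v.size
    # cumulative weight/mean below-or-at each level -> background class for
    # the midpoint threshold just above that level
    w0 = np.cumsum(counts)[:-1] / n
    sum0 = np.cumsum(counts * levels)[:-1]
    total = float(np.sum(counts * levels))
    mu0 = sum0 / (w0 * n)
    w1 = 1.0 - w0
    mu1 = (total - sum0) / (w1 * n)
    between = w0 * w1 * (mu0 - mu1) ** 2
    # ties (within fp round-off of the max) take the lowest threshold
    idx = int(np.flatnonzero(between >= between.max() * (1.0 - 1e-9))[0])
    return float((levels[idx] + levels[idx + 1]) / 2.0)


def binarize(block_pixels: np.ndarray, threshold: float) -> np.ndarray:
    """Foreground = pixels strictly greater than the threshold."""
    return np.asarray(block_pixels) > threshold


def label_components(binary_block: np.ndarray) -> tuple[np.ndarray, int]:
    """8-connected component labelling; labels 1..n in row-major first-encounter order."""
    binary_block = np.asarray(binary_block).astype(bool)
    labels, count = ndimage.label(binary_block, structure=_STRUCTURE_8)
    return labels, int(count)


def patch_statistics(block_pixels: np.ndarray, min_patch_area_px: int = 1) -> PatchStats:
    """Otsu-binarize a block, label 8-connected patches, and summarize them.

    Components smaller than ``min_patch_area_px`` are discarded (default 1 =
    keep everything, including single-pixel patches). Degenerate (constant)
    blocks yield patch_count 0 with NaN means and threshold.
    """
    block = np.asarray(block_pixels, dtype=np.float64)
    nan = float("nan")
    t = otsu_threshold(block)
    if math.isnan(t):
        return PatchStats(0, nan, nan, nan, nan)
    fg = binarize(block, t)
    labels, count = label_components(fg)
    if count == 0:  # cannot happen for a non-degenerate Otsu split, but be safe
        return PatchStats(0, nan, nan, nan, t)
    areas = ndimage.sum_labels(fg, labels, index=np.arange(1, count + 1))
    keep = np.flatnonzero(areas >= min_patch_area_px) + 1
    if keep.size == 0:
        return PatchStats(0, nan, nan, nan, t)
    kept_mask = np.isin(labels, keep)
    kept_areas = areas[keep - 1]
    patch_means = ndimage.mean(block, labels, index=keep)
    return PatchStats(
        patch_count=int(keep.size),
        mean_patch_area_px=float(kept_areas.mean()),
        mean_fg_intensity=float(block[kept_mask].mean()),
        mean_intensity_per_patch=float(np.mean(patch_means)),
        otsu_threshold=t,
    )
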