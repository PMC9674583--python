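"""Rotation/offset-robust Haralick texture features from grid blocks.

For each block a gray-level co-occurrence matrix (GLCM) is accumulated at 12
spatial offsets — distances 1..4 at each of the angles 0°, 45° and 90° — and
Energy, Contrast and Homogeneity are computed per GLCM. The 12 values of each
feature form a 4 (distance) x 3 (angle) matrix whose leading singular value,
scaled by 1/sqrt(12), is the invariant form: a single scalar robust to
spatial offset and to rotations that permute the angle columns. Heterogeneity
is defined as 1 - homogeneity (invariant form).

GLCMs are accumulated directly from integer offset displacements with numpy,
because the required offsets are specified as literal (dx, dy) pairs
(including diagonal displacements (k, k) whose Euclidean length is not an
integer number of pixels).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .config import GlcmConfig

logger = logging.getLogger(__name__)

#: Angle families of the default offset list, keyed by (dx==0, dy==0) pattern.
_ANGLES = ("0deg", "45deg", "90deg")


@dataclass(frozen=True)
class TextureFeatures:
    energy: float
    contrast: float
    homogeneity: float
    heterogeneity: float


def quantize_block(block_pixels: np.ndarray, cfg: GlcmConfig | None = None) -> np.ndarray:
    """Linearly bin intensities into ``cfg.levels`` gray levels.

    'block_minmax' spans the block's own [min, max]; the maximum maps to the
    top level, a constant block maps entirely to level 0. 'global_range'
    spans ``cfg.global_range`` with clipping.
    """
    cfg = cfg or GlcmConfig()
    v = np.asarray(block_pixels, dtype=np.float64)
    if v.size == 0:
        raise ValueError("empty block")
    if cfg.quantization == "block_minmax":
        lo, hi = float(v.min()), float(v.max())
    else:
        lo, hi = cfg.global_range
        v = np.clip(v, lo, hi)
    if hi <= lo:
        return np.zeros(v.shape, dtype=np.intp)
    q = np.floor(cfg.levels * (v - lo) / (hi - lo)).astype(np.intp)
    return np.minimum(q, cfg.levels - 1)


def compute_glcm(q_block: np.ndarray, offset: tuple[int, int],
                 cfg: GlcmConfig | None = None) -> np.ndarray | None:
    """Co-occurrence matrix of a quantized block at one (dx, dy) offset.

    Counts pairs (q[r, c], q[r + dy, c + dx]) over all in-bounds positions,
    adds the transpose if ``cfg.symmetric``, and normalizes to sum 1. Returns
    None (undefined) when the offset span does not fit in the block.
    """
    cfg = cfg or GlcmConfig()
    q = np.asarray(q_block)
    dx, dy = int(offset[0]), int(offset[1])
    h, w = q.shape
    r0, r1 = max(0, -dy), h - max(0, dy)
    c0, c1 = max(0, -dx), w - max(0, dx)
    if r1 <= r0 or c1 <= c0:
        logger.warning("offset (dx=%d, dy=%d) exceeds block shape %s; GLCM undefined",
                       dx, dy, q.shape)
        return None
    a = q[r0:r1, c0:c1].ravel()
    b = q[r0 + dy:r1 + dy, c0 + dx:c1 + dx].ravel()
    L = cfg.levels
    counts = np.bincount(a * L + b, minlength=L * L).reshape(L, L).astype(np.float64)
    if cfg.symmetric:
        counts = counts + counts.T
    return counts / counts.sum()


def haralick_feature(glcm: np.ndarray, which: str, homogeneity_form: str = "squared") -> float:
    """Energy, contrast or homogeneity of a normalized GLCM.

    energy = sum p^2 ; contrast = sum (i-j)^2 p ; homogeneity =
    sum p / (1 + (i-j)^2) (or 1 + |i-j| with homogeneity_form='abs').
    """
    p = np.asarray(glcm, dtype=np.float64)
    if which == "energy":
        return float(np.sum(p * p))
    i, j = np.indices(p.shape)
    d = i - j
    if which == "contrast":
        return float(np.sum(d * d * p))
    if which == "homogeneity":
        if homogeneity_form == "abs":
            return float(np.sum(p / (1.0 + np.abs(d))))
        return float(np.sum(p / (1.0 + d * d)))
    raise ValueError(f"unknown Haralick feature {which!r}")


def invariant_form(feature_matrix: np.ndarray) -> float:
    """Leading singular value of the distance x angle feature matrix, scaled.

    The scale 1/sqrt(rows*cols) makes a constant matrix of value c return
    exactly c, and column permutations (angle relabelling under rotation)
    leave the result unchanged.
    """
    m = np.asarray(feature_matrix, dtype=np.float64)
    if np.isnan(m).any():
        bad = np.argwhere(np.isnan(m))[0]
        raise ValueError(
            f"undefined feature cell at distance index {bad[0]}, angle index {bad[1]} "
            "(GLCM undefined for that offset)"
        )
    return float(np.linalg.svd(m, compute_uv=False)[0] / math.sqrt(m.size))


def _offset_position(offset: tuple[int, int]) -> tuple[int, int]:
    """(distance index, angle index) of an offset in the feature matrix."""
    dx, dy = offset
    if dx == 0:
        return abs(dy) - 1, 0
    if dy == 0:
        return abs(dx) - 1, 2
    if abs(dx) == abs(dy):
        return abs(dx) - 1, 1
    raise ValueError(f"offset {offset} does not belong to a 0/45/90-degree family")


def block_texture(block_pixels: np.ndarray, cfg: GlcmConfig | None = None) -> TextureFeatures:
    """Invariant-form Energy/Contrast/Homogeneity (and Heterogeneity) of a block.

    Quantizes, accumulates one GLCM per configured offset, evaluates the
    three Haralick features per GLCM, arranges each feature as a
    distance x angle matrix, and reduces it with :func:`invariant_form`.
    A constant block yields energy 1, contrast 0, homogeneity 1,
    heterogeneity 0. Blocks smaller than the largest offset span are
    rejected.
    """
    cfg = cfg or GlcmConfig()
    block = np.asarray(block_pixels)
    max_span = max(max(abs(dx), abs(dy)) for dx, dy in cfg.offsets)
    if min(block.shape) <= max_span:
        raise ValueError(
            f"block shape {block.shape} too small for offsets spanning {max_span} pixels"
        )
    q = quantize_block(block, cfg)
    n_dist = max(max(abs(dx), abs(dy)) for dx, dy in cfg.offsets)
    mats = {f: np.full((n_dist, len(_ANGLES)), np.nan) for f in ("energy", "contrast", "homogeneity")}
    for off in cfg.offsets:
        g = compute_glcm(q, off, cfg)
        if g is None:
            raise ValueError(f"GLCM undefined for offset {off} on block shape {block.shape}")
        r, c = _offset_position(off)
        for f in mats:
            mats[f][r, c] = haralick_feature(g, f, cfg.homogeneity_form)
    energy = invariant_form(mats["energy"])
    contrast = invariant_form(mats["contrast"])
    homogeneity = invariant_form(mats["homogeneity"])
    return TextureFeatures(
        energy=energy,
        contrast=contrast,
        homogeneity=homogeneity,
        heterogeneity=1.0 - homogeneity,
    )
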