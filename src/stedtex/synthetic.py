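"""Synthetic STED-like image generator with ground truth.

Emulates deconvolved super-resolution images of a cell periphery: a
lamellipodium-like ROI containing bright sub-diffraction clusters rendered as
isotropic Gaussian spots over a constant background, with optional per-pixel
Poisson (shot) noise. Cluster placement is a homogeneous spatial Poisson
process restricted to the ROI, so spatial structure beyond count, size and
per-cluster intensity is deliberately absent — those three knobs are exactly
the quantities the downstream pipeline measures.

Two presets mimic the study conditions: a "control-like" regime and an
"invasive-like" regime with twice the cluster density, 1.5x the cluster
radius and 0.7x the peak intensity, mirroring the direction of the reported
phenotype differences (more clusters, ~50% larger, lower per-cluster pixel
intensity).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import IntensityImage, RoiMask, write_image, write_labels_table, write_mask

#: Reference block area (100 x 100 px) that ``count_per_block`` refers to.
BLOCK_AREA_PX = 100 * 100

#: Minimum image edge: one grid block.
MIN_EDGE_PX = 100


@dataclass(frozen=True)
class ClusterSpec:
    """Cluster population parameters.

    count_per_block : expected clusters per 100x100-px block of ROI area
        (>= 0; 0 is the degenerate no-signal limit).
    radius_px : mean Gaussian sigma of a cluster, in pixels.
    radius_cv : coefficient of variation of the radius (lognormal sizes).
    peak_intensity : mean peak photon count of a cluster.
    intensity_cv : coefficient of variation of the peak.
    """

    count_per_block: float
    radius_px: float
    radius_cv: float = 0.0
    peak_intensity: float = 100.0
    intensity_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.count_per_block < 0:
            raise ValueError("count_per_block must be >= 0")
        if self.radius_px <= 0 or self.peak_intensity <= 0:
            raise ValueError("radius_px and peak_intensity must be > 0")
        if self.radius_cv < 0 or self.intensity_cv < 0:
            raise ValueError("cv fields must be >= 0")


@dataclass(frozen=True)
class SyntheticSpec:
    image_height_px: int = 512
    image_width_px: int = 512
    pixel_size_nm: float = 25.0
    background_level: float = 10.0
    noise_model: str = "poisson"
    roi_shape: str = "band"
    cluster: ClusterSpec = ClusterSpec(count_per_block=8.0, radius_px=2.0,
                                       radius_cv=0.25, peak_intensity=120.0,
                                       intensity_cv=0.3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height_px < MIN_EDGE_PX or self.image_width_px < MIN_EDGE_PX:
            raise ValueError(
                f"image dimensions ({self.image_height_px}, {self.image_width_px}) are "
                f"smaller than one {MIN_EDGE_PX}x{MIN_EDGE_PX} grid block"
            )
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")
        if self.noise_model not in ("poisson", "none"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if self.roi_shape not in ("band", "polygon"):
            raise ValueError(f"unknown roi_shape {self.roi_shape!r}")


@dataclass(frozen=True)
class GroundTruth:
    """Every placed cluster: subpixel (row, col) centre, sigma, peak."""

    cluster_centres: tuple[tuple[float, float], ...]
    cluster_radii_px: tuple[float, ...]
    cluster_peaks: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.cluster_centres)
        if len(self.cluster_radii_px) != n or len(self.cluster_peaks) != n:
            raise ValueError("ground-truth lists must have equal lengths")

    def __len__(self) -> int:
        return len(self.cluster_centres)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "cluster_centres": [list(c) for c in self.cluster_centres],
            "cluster_radii_px": list(self.cluster_radii_px),
            "cluster_peaks": list(self.cluster_peaks),
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            cluster_centres=tuple((float(r), float(c)) for r, c in d["cluster_centres"]),
            cluster_radii_px=tuple(float(v) for v in d["cluster_radii_px"]),
            cluster_peaks=tuple(float(v) for v in d["cluster_peaks"]),
        )


def control_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """Default control-like imaging regime."""
    return dataclasses.replace(SyntheticSpec(seed=seed), **overrides)


def invasive_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """Invasive-like regime: control with count x2, radius x1.5, peak x0.7."""
    base = SyntheticSpec(seed=seed)
    c = base.cluster
    cluster = dataclasses.replace(
        c,
        count_per_block=c.count_per_block * 2.0,
        radius_px=c.radius_px * 1.5,
        peak_intensity=c.peak_intensity * 0.7,
    )
    return dataclasses.replace(base, cluster=cluster, **overrides)


def _roi_mask(spec: SyntheticSpec) -> np.ndarray:
    """Lamellipodium-like ROI: bottom band (~30% of rows) or a half-ellipse bump."""
    h, w = spec.image_height_px, spec.image_width_px
    mask = np.zeros((h, w), dtype=bool)
    if spec.roi_shape == "band":
        mask[int(round(0.7 * h)):, :] = True
    else:
        rr, cc = np.mgrid[0:h, 0:w]
        # half-ellipse against the bottom edge, centred horizontally
        mask = ((rr - (h - 1)) / (0.45 * h)) ** 2 + ((cc - (w - 1) / 2) / (0.40 * w)) ** 2 <= 1.0
    return mask


def _lognormal(rng: np.random.Generator, mean: float, cv: float, n: int) -> np.ndarray:
    if cv == 0:
        return np.full(n, mean)
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size=n)


def _render_spot(img: np.ndarray, r: float, c: float, sigma: float, peak: float) -> None:
    h, w = img.shape
    ext = int(math.ceil(4.0 * sigma))
    r0, r1 = max(0, int(r) - ext), min(h, int(r) + ext + 1)
    c0, c1 = max(0, int(c) - ext), min(w, int(c) + ext + 1)
    rr = np.arange(r0, r1, dtype=np.float64)[:, None]
    cc = np.arange(c0, c1, dtype=np.float64)[None, :]
    img[r0:r1, c0:c1] += peak * np.exp(-((rr - r) ** 2 + (cc - c) ** 2) / (2.0 * sigma * sigma))


def generate_cell_image(spec: SyntheticSpec) -> tuple[IntensityImage, RoiMask, GroundTruth]:
    """Render one synthetic cell image with its ROI mask and ground truth.

    The number of clusters is Poisson with mean
    ``count_per_block * roi_area / (100*100)``; centres fall uniformly on ROI
    pixels with uniform subpixel jitter, radii and peaks are lognormal with
    the configured means and CVs, and spots add onto the constant background.
    Identical spec (including seed) gives bit-identical outputs.
    """
    rng = np.random.default_rng(spec.seed)
    mask = _roi_mask(spec)
    img = np.full(mask.shape, float(spec.background_level))

    fg_rows, fg_cols = np.nonzero(mask)
    expected = spec.cluster.count_per_block * fg_rows.size / BLOCK_AREA_PX
    n = int(rng.poisson(expected)) if expected > 0 else 0

    centres: list[tuple[float, float]] = []
    radii: list[float] = []
    peaks: list[float] = []
    if n > 0:
        idx = rng.integers(0, fg_rows.size, size=n)
        jit = rng.uniform(0.0, 1.0, size=(n, 2))
        sig = _lognormal(rng, spec.cluster.radius_px, spec.cluster.radius_cv, n)
        amp = _lognormal(rng, spec.cluster.peak_intensity, spec.cluster.intensity_cv, n)
        for k in range(n):
            r = fg_rows[idx[k]] + jit[k, 0]
            c = fg_cols[idx[k]] + jit[k, 1]
            _render_spot(img, r, c, float(sig[k]), float(amp[k]))
            centres.append((float(r), float(c)))
            radii.append(float(sig[k]))
            peaks.append(float(amp[k]))

    if spec.noise_model == "poisson":
        img = rng.poisson(img).astype(np.float64)

    gt = GroundTruth(tuple(centres), tuple(radii), tuple(peaks))
    return IntensityImage(img, spec.pixel_size_nm), RoiMask(mask), gt


def rotate_image_90(image: IntensityImage, k: int) -> IntensityImage:
    """Lossless 90-degree rotation (k quarter-turns counterclockwise, k in {1,2,3})."""
    if k not in (1, 2, 3):
        raise ValueError(f"k must be 1, 2 or 3, got {k}")
    return IntensityImage(np.rot90(image.pixels, k=k).copy(), image.pixel_size_nm)


def _derive_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def generate_group_dataset(control: SyntheticSpec, invasive: SyntheticSpec,
                           n_images_per_group: int, seed: int,
                           out_dir: str | Path,
                           group_names: tuple[str, str] = ("control", "invasive"),
                           ) -> pd.DataFrame:
    """Write a two-group synthetic dataset to ``out_dir``.

    Produces 16-bit TIFF images, 8-bit mask TIFFs, per-image ground-truth
    JSON, and a labels CSV (image_path, mask_path, group). Per-image seeds
    derive deterministically from the master seed, so the same master seed
    reproduces the directory byte for byte.
    """
    if n_images_per_group < 1:
        raise ValueError("n_images_per_group must be >= 1")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise OSError(f"cannot create dataset directory {out_dir}: {e}") from e

    children = np.random.SeedSequence(seed).spawn(2 * n_images_per_group)
    rows = []
    specs = (control, invasive)
    for g, (gname, spec) in enumerate(zip(group_names, specs)):
        for i in range(n_images_per_group):
            child = children[g * n_images_per_group + i]
            ispec = dataclasses.replace(spec, seed=_derive_seed(child))
            image, mask, gt = generate_cell_image(ispec)
            stem = f"{gname}_{i:03d}"
            img_path = out_dir / f"{stem}.tif"
            mask_path = out_dir / f"{stem}_mask.tif"
            try:
                write_image(image, img_path)
                write_mask(mask, mask_path)
                gt.to_json(out_dir / f"{stem}_groundtruth.json")
            except OSError as e:
                raise OSError(f"failed writing dataset files under {out_dir}: {e}") from e
            rows.append({"image_path": img_path.name, "mask_path": mask_path.name,
                         "group": gname})
    labels = pd.DataFrame(rows)
    write_labels_table(labels, out_dir / "labels.csv")
    return labels
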