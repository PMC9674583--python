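"""On-disk contract of the pipeline: images, ROI masks, feature tables, labels.

Intensity images are single-channel 2-D TIFF (or PNG); the physical pixel
size always comes from configuration, never from file metadata, because tag
conventions vary across acquisition software. Loaders never rescale
intensities. Coordinates are 0-based (row, col) with the origin at the
top-left and half-open block bounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

#: Documented feature-table schema, one row per selected block.
#: ``otsu_threshold`` travels with the patch statistics as an extra
#: diagnostic column; readers require the core columns and tolerate extras.
FEATURE_COLUMNS = [
    "image_id",
    "group",
    "block_row",
    "block_col",
    "n_pixels_in_block",
    "patch_count",
    "mean_patch_area_px",
    "mean_fg_intensity",
    "mean_intensity_per_patch",
    "otsu_threshold",
    "energy",
    "contrast",
    "homogeneity",
    "heterogeneity",
]

#: Columns whose absence on read is an error (the documented core schema).
REQUIRED_FEATURE_COLUMNS = [c for c in FEATURE_COLUMNS if c != "otsu_threshold"]


@dataclass
class IntensityImage:
    """A 2-D single-channel intensity grid with physical pixel size (nm)."""

    pixels: np.ndarray
    pixel_size_nm: float = 25.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(
                f"intensity image must be 2-D single-channel, got shape {self.pixels.shape}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("intensity image contains non-finite values")
        if np.any(self.pixels < 0):
            raise ValueError("intensity image contains negative values")
        if self.pixel_size_nm <= 0:
            raise ValueError(f"pixel_size_nm must be > 0, got {self.pixel_size_nm}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class RoiMask:
    """Binary markup of the analysed region; shape matches the paired image."""

    pixels: np.ndarray = field()

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise ValueError(f"ROI mask must be 2-D, got shape {self.pixels.shape}")
        if not self.pixels.any():
            raise ValueError("empty markup: ROI mask has no foreground pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def _load_array(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    return np.asarray(iio.imread(path))


def read_image(path: str | Path, pixel_size_nm: float = 25.0) -> IntensityImage:
    """Read a single-channel 2-D image; intensities are preserved as stored.

    The pixel size is attached from the argument/config, not read from file
    metadata. Multi-channel or 3-D inputs are rejected.
    """
    path = Path(path)
    arr = _load_array(path)
    if arr.ndim != 2:
        raise ValueError(
            f"{path}: expected a single-channel 2-D image, got shape {arr.shape} "
            f"({arr.shape[-1] if arr.ndim == 3 else arr.ndim} channels/dims)"
        )
    return IntensityImage(arr, pixel_size_nm=pixel_size_nm)


def write_image(image: IntensityImage | np.ndarray, path: str | Path) -> None:
    """Write an intensity image as 16-bit unsigned TIFF.

    Values are rounded and clipped to [0, 65535]; integer inputs in range
    round-trip bit-exactly.
    """
    arr = image.pixels if isinstance(image, IntensityImage) else np.asarray(image)
    q = np.clip(np.rint(arr), 0, 65535).astype(np.uint16)
    tifffile.imwrite(Path(path), q)


def read_mask(path: str | Path, expected_shape: tuple[int, int] | None = None) -> RoiMask:
    """Read a binary ROI mask; any nonzero pixel counts as foreground.

    A mask with values other than {0, max} is accepted with a logged warning.
    All-zero masks are rejected (empty markup), as are shape mismatches
    against ``expected_shape``.
    """
    path = Path(path)
    arr = _load_array(path)
    if arr.ndim != 2:
        raise ValueError(f"{path}: mask must be 2-D, got shape {arr.shape}")
    if expected_shape is not None and tuple(arr.shape) != tuple(expected_shape):
        raise ValueError(
            f"{path}: mask shape {tuple(arr.shape)} does not match "
            f"image shape {tuple(expected_shape)}"
        )
    values = np.unique(arr)
    nonzero = values[values != 0]
    if nonzero.size > 1:
        logger.warning(
            "%s: mask is not strictly binary (values %s); treating all nonzero as foreground",
            path, values.tolist(),
        )
    if not (arr != 0).any():
        raise ValueError(f"{path}: empty markup (all-zero mask)")
    return RoiMask(arr != 0)


def write_mask(mask: RoiMask | np.ndarray, path: str | Path) -> None:
    """Write a binary mask as 8-bit (0 outside, 255 inside) TIFF or PNG."""
    arr = mask.pixels if isinstance(mask, RoiMask) else np.asarray(mask)
    out = np.where(arr.astype(bool), 255, 0).astype(np.uint8)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, out)
    else:
        iio.imwrite(path, out)


def write_feature_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write the per-block feature table as CSV.

    Undefined statistics (NaN, e.g. patch means when patch_count = 0) are
    written as empty fields; floats keep >= 12 significant digits so that
    read(write(x)) = x within float formatting.
    """
    df = pd.DataFrame(records)
    missing = [c for c in REQUIRED_FEATURE_COLUMNS if c not in df.columns]
    if missing and len(df) > 0:
        raise ValueError(f"feature table missing columns: {missing}")
    if len(df) == 0:
        df = pd.DataFrame(columns=FEATURE_COLUMNS)
    cols = [c for c in FEATURE_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, index=False, na_rep="", float_format="%.15g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature CSV; empty fields become NaN (undefined statistics)."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: feature table missing required columns: {missing}")
    return df


def read_labels_table(path: str | Path, require_groups: int = 1) -> pd.DataFrame:
    """Read the dataset manifest (image_path, mask_path, group).

    Relative paths resolve against the CSV's directory; every referenced file
    must exist.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in ("image_path", "mask_path", "group") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: labels table missing columns: {missing}")
    if len(df) == 0:
        raise ValueError(f"{path}: labels table is empty")
    base = path.parent
    for col in ("image_path", "mask_path"):
        resolved = [str(p) if Path(p).is_absolute() else str(base / p) for p in df[col]]
        for p in resolved:
            if not Path(p).exists():
                raise FileNotFoundError(f"{path}: referenced file does not exist: {p}")
        df[col] = resolved
    if df["group"].nunique() < require_groups:
        raise ValueError(
            f"{path}: labels table has {df['group'].nunique()} group(s), "
            f"need >= {require_groups}"
        )
    return df


def write_labels_table(df: pd.DataFrame, path: str | Path) -> None:
    df[["image_path", "mask_path", "group"]].to_csv(path, index=False)
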