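"""Orchestration: per-image feature extraction and group comparison reports.

Fail-fast policy: a malformed image, a shape-mismatched mask, or an image
with zero selected blocks aborts the run with the offending path in the
message, because silent exclusions would change the block sample underlying
the statistics. Per-image block counts and degenerate-block counts are
logged.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import io as sio
from .config import PipelineConfig
from .patches import patch_statistics
from .segmentation import build_grid, select_blocks
from .stats import GroupComparisonResult, compare_groups
from .texture import block_texture

logger = logging.getLogger(__name__)


def extract_image_features(image: sio.IntensityImage, roi: sio.RoiMask,
                           config: PipelineConfig, image_id: str = "",
                           group: str = "") -> pd.DataFrame:
    """One feature row per ROI-selected grid block of a single image."""
    blocks = build_grid(image, config.grid)
    selected = select_blocks(blocks, roi, image_shape=image.shape)
    if not selected:
        raise ValueError(f"no blocks selected for image {image_id or '<in-memory>'}")
    rows = []
    n_degenerate = 0
    for b in selected:
        px = b.extract(image.pixels)
        ps = patch_statistics(px, config.min_patch_area_px)
        tx = block_texture(px, config.glcm)
        if ps.patch_count == 0:
            n_degenerate += 1
        rows.append({
            "image_id": image_id, "group": group,
            "block_row": b.block_row, "block_col": b.block_col,
            "n_pixels_in_block": b.n_pixels,
            "patch_count": ps.patch_count,
            "mean_patch_area_px": ps.mean_patch_area_px,
            "mean_fg_intensity": ps.mean_fg_intensity,
            "mean_intensity_per_patch": ps.mean_intensity_per_patch,
            "otsu_threshold": ps.otsu_threshold,
            "energy": tx.energy, "contrast": tx.contrast,
            "homogeneity": tx.homogeneity, "heterogeneity": tx.heterogeneity,
        })
    logger.info("image %s: %d/%d blocks selected, %d degenerate",
                image_id, len(selected), len(blocks), n_degenerate)
    return pd.DataFrame(rows)


def run_extract(labels_csv: str | Path, config: PipelineConfig,
                out_csv: str | Path | None = None) -> pd.DataFrame:
    """Extract features for every image in a labels table; optionally write CSV."""
    labels = sio.read_labels_table(labels_csv)
    frames = []
    for row in labels.itertuples(index=False):
        image = sio.read_image(row.image_path, pixel_size_nm=config.pixel_size_nm)
        roi = sio.read_mask(row.mask_path, expected_shape=image.shape)
        image_id = Path(row.image_path).stem
        frames.append(extract_image_features(image, roi, config,
                                             image_id=image_id, group=row.group))
    table = pd.concat(frames, ignore_index=True)
    if out_csv is not None:
        sio.write_feature_table(table, out_csv)
    return table


def comparison_report(results: list[GroupComparisonResult], group_a: str,
                      group_b: str, config: PipelineConfig) -> dict:
    """JSON-serializable report with full config echo for provenance."""
    return {
        "group_a": group_a,
        "group_b": group_b,
        "config": config.to_dict(),
        "features": [r.to_dict() for r in results],
    }


def _report_frame(results: list[GroupComparisonResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        d = r.to_dict()
        d["notch_a_low"], d["notch_a_high"] = d.pop("notch_a")
        d["notch_b_low"], d["notch_b_high"] = d.pop("notch_b")
        rows.append(d)
    return pd.DataFrame(rows)


def run_compare(feature_csv: str | Path, group_a: str, group_b: str,
                config: PipelineConfig, out_prefix: str | Path | None = None,
                plot: bool = False) -> list[GroupComparisonResult]:
    """Compare two groups from a feature CSV and write JSON/CSV reports."""
    table = sio.read_feature_table(feature_csv)
    results = compare_groups(table, group_a, group_b, config.stats)
    if out_prefix is not None:
        out_prefix = Path(out_prefix)
        out_prefix.parent.mkdir(parents=True, exist_ok=True)
        report = comparison_report(results, group_a, group_b, config)
        Path(f"{out_prefix}.json").write_text(json.dumps(report, indent=2))
        _report_frame(results).to_csv(f"{out_prefix}.csv", index=False,
                                      float_format="%.15g")
        if plot:
            from .plotting import notched_box_figure
            fig = notched_box_figure(table, results, group_a, group_b,
                                     config.stats.features)
            fig.savefig(f"{out_prefix}_boxplots.png", dpi=150)
    return results
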