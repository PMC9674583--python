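"""Grid tiling and ROI-based block selection.

Each image is divided into a grid of fixed-size blocks starting at the
top-left corner; every block that is partially or wholly overlapped by the
expert-marked ROI enters the analysis. Bounds are half-open (row, col)
intervals so blocks tile the image without overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .config import GridConfig
from .io import IntensityImage, RoiMask


@dataclass(frozen=True)
class GridBlock:
    block_row: int
    block_col: int
    r0: int
    r1: int
    c0: int
    c1: int
    selected: bool = False

    @property
    def n_pixels(self) -> int:
        return (self.r1 - self.r0) * (self.c1 - self.c0)

    def extract(self, pixels: np.ndarray) -> np.ndarray:
        return pixels[self.r0:self.r1, self.c0:self.c1]


def build_grid(image: IntensityImage | np.ndarray, cfg: GridConfig | None = None) -> list[GridBlock]:
    """Enumerate grid blocks row-major from the top-left corner.

    Full blocks have exactly ``block_size_px ** 2`` pixels; truncated
    right/bottom remainders are included only when
    ``cfg.include_truncated_edge_blocks``. An image smaller than one block in
    either dimension is rejected.
    """
    cfg = cfg or GridConfig()
    pixels = image.pixels if isinstance(image, IntensityImage) else np.asarray(image)
    h, w = pixels.shape
    bs = cfg.block_size_px
    if h < bs or w < bs:
        raise ValueError(
            f"image shape ({h}, {w}) is smaller than one {bs}x{bs} grid block"
        )

    def edges(n: int) -> list[tuple[int, int]]:
        bounds = [(i * bs, (i + 1) * bs) for i in range(n // bs)]
        if cfg.include_truncated_edge_blocks and n % bs:
            bounds.append(((n // bs) * bs, n))
        return bounds

    blocks = []
    for br, (r0, r1) in enumerate(edges(h)):
        for bc, (c0, c1) in enumerate(edges(w)):
            blocks.append(GridBlock(br, bc, r0, r1, c0, c1))
    return blocks


def select_blocks(blocks: list[GridBlock], roi: RoiMask,
                  image_shape: tuple[int, int] | None = None) -> list[GridBlock]:
    """Return the blocks overlapped by at least one ROI-foreground pixel.

    Order is preserved; returned blocks carry ``selected=True``. The ROI
    shape is checked against ``image_shape`` when given, and must contain
    every block's bounds regardless.
    """
    if image_shape is not None and tuple(roi.shape) != tuple(image_shape):
        raise ValueError(
            f"ROI shape {tuple(roi.shape)} does not match image shape {tuple(image_shape)}"
        )
    h, w = roi.shape
    for b in blocks:
        if b.r1 > h or b.c1 > w:
            raise ValueError(
                f"block ({b.block_row}, {b.block_col}) bounds exceed ROI shape {(h, w)}"
            )
    return [replace(b, selected=True) for b in blocks if roi.pixels[b.r0:b.r1, b.c0:b.c1].any()]
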