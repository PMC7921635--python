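"""Core domain containers shared across the pipeline.

A survey consists of geo-tagged street-level frames (:class:`StreetImage`),
each paired with a per-pixel semantic label map (:class:`LabelMap`).
Advertisement pixels in a label map carry one of four content-category ids;
0 is always background. Pixel coordinates are 0-based, x to the right and
y down; geographic coordinates are WGS84 lon/lat in decimal degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Advertisement content categories, in palette-id order.
CATEGORIES: tuple[str, ...] = ("food", "alcohol", "gambling", "other")

#: Label-map palette: pixel value -> category name (0 = background).
PALETTE: dict[int, str] = {i + 1: c for i, c in enumerate(CATEGORIES)}

#: Category name -> label-map pixel value.
CATEGORY_IDS: dict[str, int] = {c: i for i, c in PALETTE.items()}

#: All pixel values that mark advertisement ("billboard") pixels.
AD_IDS: frozenset[int] = frozenset(PALETTE)


@dataclass
class StreetImage:
    """One geo-tagged frame of the survey route."""

    image_id: str
    pixels: np.ndarray  # (H, W, 3) uint8 RGB
    lon: float
    lat: float
    timestamp: str  # ISO 8601

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class LabelMap:
    """Per-pixel semantic category grid aligned to a street image."""

    image_id: str
    grid: np.ndarray  # (H, W) integer category ids, 0 = background

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ValueError("label map grid must be 2-D")
        unknown = set(np.unique(self.grid)) - {0} - set(PALETTE)
        if unknown:
            raise ValueError(f"label map contains ids outside the palette: {sorted(unknown)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape  # type: ignore[return-value]


@dataclass
class AdInstance:
    """One extracted advertisement.

    The hull is the convex polygon drawn around a connected component of
    advertisement pixels; ``filled_area_px`` counts pixels inside the filled
    hull. The crop is the source image masked to the hull and tight-cropped
    to its bounding box, so pixels outside the hull are zero. The geotag is
    inherited from the source frame (the capture point, not the physical
    billboard position).
    """

    instance_id: str
    image_id: str
    hull: np.ndarray  # (K, 2) float vertices, (x, y) pixel coordinates
    filled_area_px: int
    crop: np.ndarray  # (h, w, 3) uint8, zero outside hull
    lon: float
    lat: float
    category: str | None = None
    bbox: tuple[int, int, int, int] = field(default=(0, 0, 0, 0))  # (min_row, min_col, max_row, max_col) exclusive
    truth_id: str | None = None  # planted billboard id on synthetic fixtures
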