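"""Sliding-window dicing and overlap-averaged reconstruction.

Full-resolution fundus photographs are cut into window x window subimages at
a fixed stride (256 px windows, stride 64 by default, so an interior pixel
falls in (256/64)^2 = 16 windows). Offsets enumerate every stride multiple
per axis, plus a final edge-flush offset when the image size is not an exact
multiple, so the union of tile footprints always covers the whole image.
Tiles that barely intersect the retinal field of view ("black background"
tiles) can be flagged invalid before training/inference. At merge time each
pixel's probability is the arithmetic mean over all valid tiles covering it;
pixels no valid tile covers are NaN sentinels, never silent zeros.

Coordinates are 0-based and half-open throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ShapeError

__all__ = ["TileGrid", "dice", "filter_background", "coverage_count",
           "coverage_map", "merge"]


def _axis_offsets(size: int, window: int, stride: int) -> list[int]:
    offsets = list(range(0, size - window + 1, stride))
    if offsets[-1] != size - window:
        offsets.append(size - window)  # edge-flush tile for full coverage
    return offsets


@dataclass
class TileGrid:
    """Bookkeeping of one sliding-window decomposition."""

    image_height: int
    image_width: int
    window: int = 256
    stride: int = 64
    offsets: list[tuple[int, int]] = field(default_factory=list)
    valid_flags: np.ndarray | None = None

    def __post_init__(self):
        if self.window < 1 or not 1 <= self.stride <= self.window:
            raise ShapeError("need 1 <= stride <= window")
        if self.window > min(self.image_height, self.image_width):
            raise ShapeError(
                f"window {self.window} exceeds image "
                f"{self.image_height}x{self.image_width}; pad or skip")
        if not self.offsets:
            rows = _axis_offsets(self.image_height, self.window, self.stride)
            cols = _axis_offsets(self.image_width, self.window, self.stride)
            self.offsets = [(r, c) for r in rows for c in cols]
        for r, c in self.offsets:
            if not (0 <= r <= self.image_height - self.window
                    and 0 <= c <= self.image_width - self.window):
                raise ShapeError(f"offset ({r}, {c}) out of bounds")
        if self.valid_flags is None:
            self.valid_flags = np.ones(len(self.offsets), dtype=bool)
        else:
            self.valid_flags = np.asarray(self.valid_flags, dtype=bool)
            if self.valid_flags.shape != (len(self.offsets),):
                raise ShapeError("valid_flags length must match offsets")

    def __len__(self) -> int:
        return len(self.offsets)

    @property
    def n_valid(self) -> int:
        return int(self.valid_flags.sum())

    def valid_offsets(self):
        return [off for off, ok in zip(self.offsets, self.valid_flags) if ok]

    def to_json(self) -> str:
        return json.dumps({
            "image_height": self.image_height, "image_width": self.image_width,
            "window": self.window, "stride": self.stride,
            "offsets": [list(o) for o in self.offsets],
            "valid_flags": self.valid_flags.astype(int).tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "TileGrid":
        d = json.loads(text)
        return cls(image_height=d["image_height"], image_width=d["image_width"],
                   window=d["window"], stride=d["stride"],
                   offsets=[tuple(o) for o in d["offsets"]],
                   valid_flags=np.asarray(d["valid_flags"], dtype=bool))


def dice(image, window: int = 256, stride: int = 64):
    """Cut an image (H x W or H x W x C array, or FundusImage) into tiles.

    Returns (grid, tiles) with one tile per grid offset, in offset order.
    """
    px = np.asarray(image.pixels if hasattr(image, "pixels") else image)
    h, w = px.shape[:2]
    grid = TileGrid(image_height=h, image_width=w, window=window, stride=stride)
    tiles = [px[r:r + window, c:c + window].copy() for r, c in grid.offsets]
    return grid, tiles


def filter_background(grid: TileGrid, roi_mask, min_roi_fraction: float = 0.5
                      ) -> TileGrid:
    """Invalidate tiles whose field-of-view coverage is below the threshold.

    Tiles already invalid stay invalid; a new grid is returned.
    """
    roi = np.asarray(roi_mask).astype(bool)
    if roi.shape != (grid.image_height, grid.image_width):
        raise ShapeError(f"roi_mask shape {roi.shape} != image "
                         f"({grid.image_height}, {grid.image_width})")
    area = grid.window * grid.window
    flags = grid.valid_flags.copy()
    for i, (r, c) in enumerate(grid.offsets):
        if not flags[i]:
            continue
        frac = np.count_nonzero(roi[r:r + grid.window, c:c + grid.window]) / area
        if frac < min_roi_fraction:
            flags[i] = False
    return TileGrid(image_height=grid.image_height, image_width=grid.image_width,
                    window=grid.window, stride=grid.stride,
                    offsets=list(grid.offsets), valid_flags=flags)


def coverage_map(grid: TileGrid) -> np.ndarray:
    """Per-pixel count of valid tiles covering each pixel."""
    cov = np.zeros((grid.image_height, grid.image_width), dtype=np.int64)
    for (r, c), ok in zip(grid.offsets, grid.valid_flags):
        if ok:
            cov[r:r + grid.window, c:c + grid.window] += 1
    return cov


def coverage_count(grid: TileGrid, pixel: tuple[int, int]) -> int:
    """Number of valid tiles whose footprint contains the pixel."""
    row, col = pixel
    if not (0 <= row < grid.image_height and 0 <= col < grid.image_width):
        raise ShapeError(f"pixel {pixel} outside image "
                         f"({grid.image_height}, {grid.image_width})")
    n = 0
    for (r, c), ok in zip(grid.offsets, grid.valid_flags):
        if ok and r <= row < r + grid.window and c <= col < c + grid.window:
            n += 1
    return n


def merge(tile_predictions, grid: TileGrid) -> np.ndarray:
    """Average per-tile probability rasters back into a full-size map.

    ``tile_predictions`` holds one window x window raster per *valid* tile,
    in valid-offset order. Output pixels covered by zero valid tiles are NaN.
    """
    preds = [np.asarray(p, dtype=np.float64) for p in tile_predictions]
    offsets = grid.valid_offsets()
    if len(preds) != len(offsets):
        raise ShapeError(f"got {len(preds)} predictions for {len(offsets)} "
                         "valid tiles")
    acc = np.zeros((grid.image_height, grid.image_width))
    cnt = np.zeros((grid.image_height, grid.image_width), dtype=np.int64)
    w = grid.window
    for p, (r, c) in zip(preds, offsets):
        if p.shape != (w, w):
            raise ShapeError(f"prediction shape {p.shape} != window ({w}, {w})")
        acc[r:r + w, c:c + w] += p
        cnt[r:r + w, c:c + w] += 1
    out = np.full_like(acc, np.nan)
    covered = cnt > 0
    out[covered] = acc[covered] / cnt[covered]
    return out
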