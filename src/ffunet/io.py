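"""Reading and writing images, masks, and probability maps."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .preprocess import FundusImage
from .synthetic import LesionMask

__all__ = ["load_image", "save_image", "load_mask", "save_mask",
           "save_probability_map", "load_probability_map"]


def load_image(path) -> FundusImage:
    """Load a JPG/PNG photograph as an 8-bit-range RGB FundusImage."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=np.float64)
    return FundusImage(pixels=arr, value_range="uint8")


def save_image(image: FundusImage, path) -> None:
    px = np.clip(np.asarray(image.pixels), 0, 255).astype(np.uint8)
    Image.fromarray(px, mode="RGB").save(Path(path))


def load_mask(path, lesion_class: str = "EX") -> LesionMask:
    """Load a PNG/TIFF binary mask; any nonzero pixel is positive."""
    p = Path(path)
    if p.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(p)
    else:
        with Image.open(p) as im:
            arr = np.asarray(im.convert("L"))
    return LesionMask(pixels=arr > 0, lesion_class=lesion_class)


def save_mask(mask, path) -> None:
    """Write a binary mask as a single-channel {0, 255} PNG."""
    arr = np.asarray(mask.pixels if hasattr(mask, "pixels") else mask)
    Image.fromarray((arr.astype(bool) * np.uint8(255)), mode="L").save(Path(path))


def save_probability_map(prob: np.ndarray, path) -> None:
    """Write a probability raster as 32-bit float TIFF (NaN = uncovered)."""
    tifffile.imwrite(Path(path), np.asarray(prob, dtype=np.float32))


def load_probability_map(path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.float64)
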