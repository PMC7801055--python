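"""Fundus-photograph preprocessing.

The pipeline applied before tiling, in order:

1. ROI cropping — a fundus photograph is a bright circular field of view on
   a black border; Otsu thresholding of the luminance followed by
   largest-connected-component selection isolates the retina and its
   bounding box.
2. Gaussian denoising with a normalized 3x3 kernel (sigma = 0.8).
3. CLAHE contrast enhancement on the L channel in CIELAB space, so that
   microaneurysms / hemorrhages / vessels (nearly indistinguishable in
   colour) separate in local contrast.
4. Dataset normalization x_norm = (x - mu) / theta with per-channel mean mu
   and standard deviation theta pooled over the training images only.
5. Random geometric augmentation (flip / rotate / shift / rescale / crop
   jitter) applied identically to the image and its lesion mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import color, exposure
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.transform import AffineTransform, warp

from .errors import DegenerateInputError, ShapeError

__all__ = [
    "FundusImage", "NormStats", "BoundingBox", "AugmentConfig",
    "find_roi", "crop_to_roi", "denoise", "enhance_contrast",
    "compute_dataset_stats", "normalize", "denormalize", "augment",
    "preprocess_image",
]


@dataclass
class FundusImage:
    """An H x W x 3 raster with a recorded value range and optional ROI mask.

    value_range is "uint8" while intensities live in 0..255 and "normalized"
    after dataset normalization.
    """

    pixels: np.ndarray
    value_range: str = "uint8"
    roi_mask: np.ndarray | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ShapeError(f"expected H x W x 3 pixels, got {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ShapeError("image must have positive height and width")
        if self.roi_mask is not None:
            self.roi_mask = np.asarray(self.roi_mask).astype(bool)
            if self.roi_mask.shape != self.pixels.shape[:2]:
                raise ShapeError("roi_mask shape must match image H x W")

    @property
    def shape(self):
        return self.pixels.shape

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class NormStats:
    """Per-channel dataset mean and standard deviation."""

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=np.float64))
        object.__setattr__(self, "std", np.asarray(self.std, dtype=np.float64))
        if self.mean.shape != (3,) or self.std.shape != (3,):
            raise ShapeError("NormStats expects 3-channel mean/std")
        if not (self.std > 0).all():
            raise DegenerateInputError("std must be strictly positive per channel")

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "std": self.std.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "NormStats":
        return cls(mean=np.asarray(d["mean"]), std=np.asarray(d["std"]))


@dataclass(frozen=True)
class BoundingBox:
    """0-based, half-open pixel box [row_start, row_end) x [col_start, col_end)."""

    row_start: int
    row_end: int
    col_start: int
    col_end: int

    def __post_init__(self):
        if not (0 <= self.row_start < self.row_end and 0 <= self.col_start < self.col_end):
            raise ShapeError(f"degenerate bounding box {self}")

    @property
    def height(self) -> int:
        return self.row_end - self.row_start

    @property
    def width(self) -> int:
        return self.col_end - self.col_start

    def slices(self):
        return (slice(self.row_start, self.row_end),
                slice(self.col_start, self.col_end))


def _luminance(pixels: np.ndarray) -> np.ndarray:
    return color.rgb2gray(np.clip(pixels, 0, 255) / 255.0)


def find_roi(image: FundusImage) -> tuple[BoundingBox, np.ndarray]:
    """Locate the circular field of view on the black camera border.

    Otsu's threshold on luminance defines foreground; the largest
    8-connected foreground component is the ROI. Returns its bounding box
    and the component itself as a boolean mask. Raises on constant images,
    for which no threshold exists.
    """
    lum = _luminance(image.pixels)
    if lum.max() - lum.min() < 1e-12:
        raise DegenerateInputError("constant image: no foreground/background split")
    thresh = threshold_otsu(lum)
    fg = lum > thresh
    if not fg.any():  # pathological: everything at/below threshold
        raise DegenerateInputError("Otsu threshold leaves no foreground")
    labels = label(fg, connectivity=2)
    largest = max(regionprops(labels), key=lambda r: r.area)
    roi = labels == largest.label
    r0, c0, r1, c1 = largest.bbox
    return BoundingBox(r0, r1, c0, c1), roi


def crop_to_roi(image: FundusImage, mask: np.ndarray | None = None):
    """Crop an image (and optionally an aligned mask) to its ROI box."""
    box, roi = find_roi(image)
    sl = box.slices()
    cropped = FundusImage(pixels=image.pixels[sl], value_range=image.value_range,
                          roi_mask=roi[sl])
    if mask is None:
        return cropped, box
    mask = np.asarray(mask)
    if mask.shape != image.pixels.shape[:2]:
        raise ShapeError("mask must match image H x W")
    return cropped, box, mask[sl]


# normalized 3x3 Gaussian kernel, sigma = 0.8
_G1 = np.exp(-np.arange(-1, 2) ** 2 / (2 * 0.8**2))
_G1 /= _G1.sum()
GAUSSIAN_KERNEL_3X3 = np.outer(_G1, _G1)


def denoise(image: FundusImage) -> FundusImage:
    """Suppress sensor noise with a 3x3 Gaussian filter (sigma 0.8)."""
    if image.value_range != "uint8":
        raise ShapeError("denoise expects an image in the 0..255 range")
    px = image.pixels.astype(np.float64)
    out = np.stack(
        [ndimage.convolve(px[..., c], GAUSSIAN_KERNEL_3X3, mode="reflect")
         for c in range(3)], axis=-1)
    return FundusImage(pixels=out, value_range="uint8", roi_mask=image.roi_mask)


def enhance_contrast(image: FundusImage, *, clip_limit: float = 0.02,
                     tile_grid: int = 8) -> FundusImage:
    """Contrast-limited adaptive histogram equalization (CLAHE).

    Applied to the L channel of CIELAB so chromaticity is untouched;
    clip_limit is on scikit-image's normalized 0..1 scale and tile_grid
    gives the number of contextual tiles per axis.
    """
    px = np.clip(image.pixels, 0, 255) / 255.0
    lab = color.rgb2lab(px)
    lum = lab[..., 0] / 100.0
    h, w = lum.shape
    kernel = (max(1, h // tile_grid), max(1, w // tile_grid))
    if lum.max() - lum.min() < 1e-12:
        eq = lum  # flat histogram: equalization is the identity
    else:
        eq = exposure.equalize_adapthist(np.clip(lum, 0, 1), kernel_size=kernel,
                                         clip_limit=clip_limit)
    lab = lab.copy()
    lab[..., 0] = eq * 100.0
    out = np.clip(color.lab2rgb(lab), 0.0, 1.0) * 255.0
    return FundusImage(pixels=out, value_range="uint8", roi_mask=image.roi_mask)


def compute_dataset_stats(images) -> NormStats:
    """Per-channel mean/std pooled over all pixels of all images (single pass)."""
    n = 0
    s = np.zeros(3)
    s2 = np.zeros(3)
    count = 0
    for img in images:
        px = np.asarray(img.pixels if hasattr(img, "pixels") else img,
                        dtype=np.float64)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ShapeError(f"expected H x W x 3 image, got {px.shape}")
        s += px.sum(axis=(0, 1))
        s2 += (px**2).sum(axis=(0, 1))
        n += px.shape[0] * px.shape[1]
        count += 1
    if count == 0:
        raise ValueError("compute_dataset_stats requires at least one image")
    mean = s / n
    var = s2 / n - mean**2
    var = np.maximum(var, 0.0)
    if not (var > 0).all():
        raise DegenerateInputError("pooled per-channel variance is zero")
    return NormStats(mean=mean, std=np.sqrt(var))


def normalize(image: FundusImage, stats: NormStats) -> FundusImage:
    """x_norm = (x - mu) / theta, per channel."""
    px = (image.pixels.astype(np.float64) - stats.mean) / stats.std
    return FundusImage(pixels=px, value_range="normalized", roi_mask=image.roi_mask)


def denormalize(image: FundusImage, stats: NormStats) -> FundusImage:
    px = image.pixels * stats.std + stats.mean
    return FundusImage(pixels=px, value_range="uint8", roi_mask=image.roi_mask)


@dataclass(frozen=True)
class AugmentConfig:
    """Geometric augmentation ranges. All defaults are mild, label-preserving
    perturbations; probabilities/ranges of zero give the identity transform."""

    flip_prob: float = 0.5
    rotation_deg: float = 15.0
    shift_fraction: float = 0.10
    rescale_range: tuple[float, float] = (0.9, 1.1)


def augment(image: FundusImage, mask: np.ndarray, seed: int,
            config: AugmentConfig = AugmentConfig()):
    """Apply one random geometric transform identically to image and mask.

    The image is resampled bilinearly and the mask with nearest-neighbour
    interpolation, so the mask stays strictly binary. A fixed seed fixes the
    transform.
    """
    mask = np.asarray(mask)
    if mask.shape != image.pixels.shape[:2]:
        raise ShapeError(f"mask shape {mask.shape} != image H x W "
                         f"{image.pixels.shape[:2]}")
    rng = np.random.default_rng(seed)
    h, w = mask.shape

    do_flip = rng.uniform() < config.flip_prob
    angle = rng.uniform(-config.rotation_deg, config.rotation_deg)
    dy = rng.uniform(-config.shift_fraction, config.shift_fraction) * h
    dx = rng.uniform(-config.shift_fraction, config.shift_fraction) * w
    lo, hi = config.rescale_range
    scale = rng.uniform(lo, hi)

    px = image.pixels.astype(np.float64)
    msk = mask.astype(np.float64)
    if do_flip:
        px = px[:, ::-1]
        msk = msk[:, ::-1]

    identity = (angle == 0.0 and dx == 0.0 and dy == 0.0 and scale == 1.0)
    if not identity:
        centre = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
        tf = (AffineTransform(translation=-centre)
              + AffineTransform(rotation=np.deg2rad(angle), scale=scale)
              + AffineTransform(translation=centre + np.array([dx, dy])))
        px = warp(px, tf.inverse, order=1, mode="constant", cval=0.0,
                  preserve_range=True)
        msk = warp(msk, tf.inverse, order=0, mode="constant", cval=0.0,
                   preserve_range=True)
    out_img = FundusImage(pixels=px, value_range=image.value_range)
    return out_img, (msk > 0.5).astype(mask.dtype)


def preprocess_image(image: FundusImage, stats: NormStats | None = None,
                     mask: np.ndarray | None = None):
    """Run crop -> denoise -> CLAHE (-> normalize) on one image.

    Returns (processed image, bounding box[, cropped mask]). Normalization is
    applied only when dataset stats are supplied.
    """
    if mask is not None:
        cropped, box, mask_c = crop_to_roi(image, mask)
    else:
        cropped, box = crop_to_roi(image)
    out = enhance_contrast(denoise(cropped))
    if stats is not None:
        out = normalize(out, stats)
    if mask is not None:
        return out, box, mask_c
    return out, box
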