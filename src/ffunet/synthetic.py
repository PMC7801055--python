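"""Synthetic fundus-like images with paired lesion masks.

The generator emulates the statistical structure the segmentation pipeline
assumes, not retinal anatomy: a bright, warm-toned circular field of view on
a black camera border, dark curvilinear vessel-like structures, and one of
four lesion classes stamped at its characteristic spatial scale —

  MA  microaneurysms : tiny dark dots (1-3 px radius)
  EX  hard exudates  : bright compact blobs (5-15 px)
  SE  soft exudates  : pale, larger fuzzy blobs (8-20 px)
  HE  hemorrhages    : dark irregular elliptical patches (6-18 px)

Lesions are anti-aliased discs/ellipses with class-dependent intensity
offsets (bright for EX/SE, dark for MA/HE); Gaussian pixel noise is added
last so the denoising stage has genuine work to do. Everything is driven by
one integer seed: identical configs reproduce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError
from .preprocess import FundusImage

__all__ = ["SynthConfig", "LesionMask", "LESION_CLASSES", "CLASS_DEFAULTS",
           "generate_fundus", "generate_fundus_with_params", "generate_dataset",
           "rasterize_lesions"]

LESION_CLASSES = ("MA", "EX", "SE", "HE")

# (count range, radius range [px], signed intensity offset) per class;
# scales respect MA << EX/SE/HE
CLASS_DEFAULTS = {
    "MA": {"count": (3, 10), "radius": (1.0, 3.0), "offset": -60.0},
    "EX": {"count": (2, 6), "radius": (5.0, 15.0), "offset": +70.0},
    "SE": {"count": (1, 4), "radius": (8.0, 20.0), "offset": +50.0},
    "HE": {"count": (1, 5), "radius": (6.0, 18.0), "offset": -70.0},
}

_BASE_COLOR = np.array([185.0, 95.0, 45.0])  # warm retinal background (RGB)


@dataclass(frozen=True)
class LesionMask:
    """H x W binary raster for one lesion class, pixel-aligned with its image."""

    pixels: np.ndarray
    lesion_class: str = "EX"

    def __post_init__(self):
        px = np.asarray(self.pixels).astype(bool)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 2:
            raise ConfigurationError(f"mask must be 2-D, got shape {px.shape}")

    @property
    def shape(self):
        return self.pixels.shape

    def positive_count(self) -> int:
        return int(np.count_nonzero(self.pixels))


@dataclass(frozen=True)
class SynthConfig:
    image_height: int = 512
    image_width: int = 512
    disc_radius_fraction: float = 0.45
    vessel_count: int = 6
    lesion_class: str = "EX"
    lesion_count_range: tuple[int, int] | None = None
    lesion_radius_range: tuple[float, float] | None = None
    lesion_intensity_offset: float | None = None
    noise_sigma: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.image_height < 16 or self.image_width < 16:
            raise ConfigurationError("image dimensions must be at least 16 px")
        if not 0.0 < self.disc_radius_fraction <= 0.5:
            raise ConfigurationError("disc_radius_fraction must be in (0, 0.5]")
        if self.lesion_class not in LESION_CLASSES:
            raise ConfigurationError(
                f"lesion_class must be one of {LESION_CLASSES}")
        if self.vessel_count < 0 or self.noise_sigma < 0:
            raise ConfigurationError("vessel_count and noise_sigma must be >= 0")
        lo, hi = self.count_range
        if not (0 <= lo <= hi):
            raise ConfigurationError(f"invalid lesion_count_range ({lo}, {hi})")
        rlo, rhi = self.radius_range
        if not (0 < rlo <= rhi):
            raise ConfigurationError(f"invalid lesion_radius_range ({rlo}, {rhi})")

    @property
    def count_range(self) -> tuple[int, int]:
        if self.lesion_count_range is not None:
            return tuple(self.lesion_count_range)
        return CLASS_DEFAULTS[self.lesion_class]["count"]

    @property
    def radius_range(self) -> tuple[float, float]:
        if self.lesion_radius_range is not None:
            return tuple(self.lesion_radius_range)
        return CLASS_DEFAULTS[self.lesion_class]["radius"]

    @property
    def intensity_offset(self) -> float:
        if self.lesion_intensity_offset is not None:
            return float(self.lesion_intensity_offset)
        return CLASS_DEFAULTS[self.lesion_class]["offset"]


def _disc_geometry(config: SynthConfig):
    h, w = config.image_height, config.image_width
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    radius = config.disc_radius_fraction * min(h, w)
    yy, xx = np.mgrid[0:h, 0:w]
    dist = np.hypot(yy - cy, xx - cx)
    return (cy, cx, radius), dist


def _soft_coverage(dist: np.ndarray, radius: float) -> np.ndarray:
    """Anti-aliased disc coverage: 1 inside, 0 outside, linear over 1 px."""
    return np.clip(radius + 0.5 - dist, 0.0, 1.0)


def rasterize_lesions(lesions, shape) -> np.ndarray:
    """Paint a binary union mask from lesion shape parameters.

    Each lesion is a dict: discs {kind: "disc", row, col, radius}, ellipses
    {kind: "ellipse", row, col, a, b, theta}. A pixel is positive when its
    centre lies inside the shape. This rasterizer is also what tests use as
    the recount oracle for the generator's masks.
    """
    h, w = shape
    mask = np.zeros((h, w), dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]
    for p in lesions:
        dy = yy - p["row"]
        dx = xx - p["col"]
        if p["kind"] == "disc":
            mask |= dy**2 + dx**2 <= p["radius"] ** 2
        else:
            ct, st = np.cos(p["theta"]), np.sin(p["theta"])
            u = dx * ct + dy * st
            v = -dx * st + dy * ct
            mask |= (u / p["a"]) ** 2 + (v / p["b"]) ** 2 <= 1.0
    return mask


def _place_lesions(config: SynthConfig, rng: np.random.Generator,
                   disc, n: int) -> list[dict]:
    """Rejection-sample non-overlapping lesions fully inside the disc."""
    cy, cx, radius = disc
    rlo, rhi = config.radius_range
    lesions: list[dict] = []
    attempts = 0
    while len(lesions) < n and attempts < 2000:
        attempts += 1
        r = rng.uniform(rlo, rhi)
        # margin keeps every positive pixel strictly inside the field of view
        max_c = radius - r - 2.0
        if max_c <= 0:
            break
        rho = np.sqrt(rng.uniform()) * max_c
        phi = rng.uniform(0, 2 * np.pi)
        row = cy + rho * np.sin(phi)
        col = cx + rho * np.cos(phi)
        sep_ok = all(np.hypot(row - q["row"], col - q["col"])
                     > r + q.get("radius", max(q.get("a", 0), q.get("b", 0))) + 2.0
                     for q in lesions)
        if not sep_ok:
            continue
        if config.lesion_class == "HE":
            ecc = rng.uniform(0.5, 0.9)
            lesions.append({"kind": "ellipse", "row": row, "col": col,
                            "a": r, "b": r * ecc,
                            "theta": rng.uniform(0, np.pi), "radius": r})
        else:
            lesions.append({"kind": "disc", "row": row, "col": col, "radius": r})
    return lesions


def _draw_vessels(img: np.ndarray, rng: np.random.Generator, disc,
                  count: int) -> None:
    """Dark random-walk curvilinear structures inside the field of view."""
    cy, cx, radius = disc
    h, w = img.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(count):
        phi = rng.uniform(0, 2 * np.pi)
        row, col = cy, cx
        heading = phi
        width = rng.uniform(1.0, 2.2)
        darken = np.zeros((h, w))
        for _step in range(int(radius * 1.4)):
            heading += rng.normal(0, 0.25)
            row += 2.0 * np.sin(heading)
            col += 2.0 * np.cos(heading)
            if np.hypot(row - cy, col - cx) > radius - 2:
                break
            r0, r1 = int(max(0, row - 3)), int(min(h, row + 4))
            c0, c1 = int(max(0, col - 3)), int(min(w, col + 4))
            d = np.hypot(yy[r0:r1, c0:c1] - row, xx[r0:r1, c0:c1] - col)
            darken[r0:r1, c0:c1] = np.maximum(
                darken[r0:r1, c0:c1], np.clip(width + 0.5 - d, 0, 1))
        img -= 45.0 * darken[..., None] * np.array([0.5, 1.0, 0.9])


def generate_fundus_with_params(config: SynthConfig):
    """Like generate_fundus, but also returns the stamped lesion parameters."""
    rng = np.random.default_rng(config.seed)
    h, w = config.image_height, config.image_width
    disc, dist = _disc_geometry(config)
    _, _, radius = disc

    fov = _soft_coverage(dist, radius)
    # mild radial vignette so the field of view is not flat
    shading = 1.0 - 0.25 * (dist / max(radius, 1.0)) ** 2
    img = fov[..., None] * shading[..., None] * _BASE_COLOR[None, None, :]
    img += fov[..., None] * rng.normal(0, 2.0, size=(h, w, 1))  # texture

    if config.vessel_count:
        _draw_vessels(img, rng, disc, config.vessel_count)

    lo, hi = config.count_range
    n = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
    lesions = _place_lesions(config, rng, disc, n)

    offset = config.intensity_offset
    yy, xx = np.mgrid[0:h, 0:w]
    for p in lesions:
        if p["kind"] == "disc":
            cov = _soft_coverage(np.hypot(yy - p["row"], xx - p["col"]),
                                 p["radius"])
        else:
            ct, st = np.cos(p["theta"]), np.sin(p["theta"])
            u = (xx - p["col"]) * ct + (yy - p["row"]) * st
            v = -(xx - p["col"]) * st + (yy - p["row"]) * ct
            d = np.sqrt((u / p["a"]) ** 2 + (v / p["b"]) ** 2)
            cov = np.clip((1.0 - d) * min(p["a"], p["b"]) + 0.5, 0.0, 1.0)
        img += offset * cov[..., None]

    if config.noise_sigma > 0:
        img += rng.normal(0, config.noise_sigma, size=img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8).astype(np.float64)

    mask = rasterize_lesions(lesions, (h, w))
    roi = dist <= radius
    image = FundusImage(pixels=img, value_range="uint8", roi_mask=roi)
    return image, LesionMask(pixels=mask, lesion_class=config.lesion_class), lesions


def generate_fundus(config: SynthConfig):
    """Generate one synthetic fundus image and its paired lesion mask."""
    image, mask, _ = generate_fundus_with_params(config)
    return image, mask


def derive_seed(base_seed: int, index: int) -> int:
    return int((base_seed * 1_000_003 + 7919 * index + 1) % (2**31 - 1))


def generate_dataset(n: int, base_config: SynthConfig,
                     negative_fraction: float = 0.25):
    """Generate n (image, mask) pairs with per-item derived seeds.

    Exactly round(n * negative_fraction) items are negatives (zero-lesion
    masks); their positions within the dataset are drawn from the base seed.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0.0 <= negative_fraction <= 1.0:
        raise ConfigurationError("negative_fraction must be in [0, 1]")
    n_neg = int(round(n * negative_fraction))
    order_rng = np.random.default_rng(derive_seed(base_config.seed, 0))
    neg_idx = set(order_rng.choice(n, size=n_neg, replace=False).tolist())
    out = []
    for i in range(n):
        cfg = replace(base_config, seed=derive_seed(base_config.seed, i + 1))
        if i in neg_idx:
            cfg = replace(cfg, lesion_count_range=(0, 0))
        out.append(generate_fundus(cfg))
    return out
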