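"""Training augmentation strategies and test-time crop transforms.

Two training strategies are provided:

* **base** — resize the shorter edge to ``resize_edge`` (512 px by
  default, aspect preserved), take a uniform random square crop of the
  backbone's input size, then a random rotation from {0, 90, 180, 270}°
  and a random vertical reflection.
* **advanced** — random-resized crop: a crop whose area is a uniform
  fraction in ``scale_range`` ([0.08, 1.0]) of the image and whose aspect
  ratio is log-uniform over ``aspect_range`` ([3/4, 4/3]), resized to the
  input size; then the same rotation/reflection; then brightness, contrast
  and saturation each scaled by an independent Uniform(1−j, 1+j) factor
  (j = 0.20).

At test time no randomness is used: the shorter edge is resized to
``resize_edge`` and either the single centre crop or the ten crops
(centre + four corners and their horizontal flips) are taken, then
normalized with ImageNet channel statistics.

All transforms consume and return ``uint8`` H×W×3 arrays; geometric order
within the advanced strategy is crop → resize → rotate → flip → jitter.
Every random choice comes from the caller-supplied ``numpy`` generator, so
a seed fully determines every augmented replicate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from PIL import Image, ImageEnhance

#: canonical ImageNet channel statistics (on the [0, 1] scale)
IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_SD = (0.229, 0.224, 0.225)

#: crop order returned by :func:`ten_crops`
CROP_IDS = ("center", "TL", "TR", "BL", "BR",
            "center_f", "TL_f", "TR_f", "BL_f", "BR_f")


@dataclass(frozen=True)
class NormalizationStats:
    mean: tuple[float, float, float] = IMAGENET_MEAN
    sd: tuple[float, float, float] = IMAGENET_SD

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sd):
            raise ValueError("normalization sd must be positive")


@dataclass(frozen=True)
class AugmentationConfig:
    strategy: str = "base"  # {base, advanced}
    target_size: int = 224
    repeats: int = 1
    resize_edge: int = 512
    scale_range: tuple[float, float] = (0.08, 1.0)
    aspect_range: tuple[float, float] = (3 / 4, 4 / 3)
    jitter_fraction: float = 0.20
    rotation_set: tuple[int, ...] = (0, 90, 180, 270)
    vflip_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in ("base", "advanced"):
            raise ValueError(f"unknown augmentation strategy {self.strategy!r}")
        if self.target_size > self.resize_edge:
            raise ValueError(
                f"target_size ({self.target_size}) must not exceed "
                f"resize_edge ({self.resize_edge})"
            )
        lo, hi = self.scale_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("scale_range must be within (0, 1]")
        if not (0 <= self.jitter_fraction < 1):
            raise ValueError("jitter_fraction must be in [0, 1)")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if any(r not in (0, 90, 180, 270) for r in self.rotation_set):
            raise ValueError("rotation_set entries must be multiples of 90 in [0, 270]")


def _as_pil(image: np.ndarray) -> Image.Image:
    if image.ndim != 3 or image.shape[2] != 3 or image.dtype != np.uint8:
        raise ValueError("expected an H x W x 3 uint8 RGB array")
    return Image.fromarray(image, mode="RGB")


def resize_shorter_edge(image: np.ndarray, edge: int) -> np.ndarray:
    """Bilinear resize so the shorter edge equals ``edge``, aspect preserved."""
    h, w = image.shape[:2]
    if min(h, w) < 8:
        raise ValueError(f"image too small to resize ({w}x{h})")
    scale = edge / min(h, w)
    new_w = max(edge, int(round(w * scale)))
    new_h = max(edge, int(round(h * scale)))
    if (new_h, new_w) == (h, w):
        return image.copy()
    pil = _as_pil(image).resize((new_w, new_h), Image.BILINEAR)
    return np.asarray(pil)


def _rotate_flip(
    image: np.ndarray,
    cfg: AugmentationConfig,
    rng: np.random.Generator,
    rotation: int | None,
    flip: bool | None,
) -> np.ndarray:
    if rotation is None:
        rotation = int(cfg.rotation_set[rng.integers(len(cfg.rotation_set))])
    if flip is None:
        flip = bool(rng.random() < cfg.vflip_prob)
    out = np.rot90(image, k=rotation // 90)
    if flip:
        out = np.flipud(out)
    return np.ascontiguousarray(out)


def base_augment(
    image: np.ndarray,
    cfg: AugmentationConfig,
    rng: np.random.Generator,
    *,
    crop_origin: tuple[int, int] | None = None,
    rotation: int | None = None,
    flip: bool | None = None,
) -> np.ndarray:
    """Resize-then-crop training transform.

    The keyword overrides pin individual random choices (used for exact
    tests of the geometry); left as ``None`` they are drawn from ``rng``.
    """
    resized = resize_shorter_edge(image, cfg.resize_edge)
    h, w = resized.shape[:2]
    t = cfg.target_size
    if h < t or w < t:
        raise ValueError(f"resized image ({w}x{h}) smaller than target {t}")
    if crop_origin is None:
        top = int(rng.integers(0, h - t + 1))
        left = int(rng.integers(0, w - t + 1))
    else:
        top, left = crop_origin
    crop = resized[top : top + t, left : left + t]
    return _rotate_flip(crop, cfg, rng, rotation, flip)


def sample_crop_geometry(
    shape: tuple[int, int], cfg: AugmentationConfig, rng: np.random.Generator
) -> tuple[int, int, int, int]:
    """Sample (top, left, height, width) for the advanced strategy.

    Area fraction ~ Uniform(scale_range); aspect ratio log-uniform over
    ``aspect_range``.  Integer side lengths are chosen so the realized
    pixel-area fraction never falls below the sampled fraction, keeping all
    realized fractions inside ``scale_range``.  After ten rejected
    proposals a central crop of the clamped aspect is used.
    """
    h_img, w_img = shape
    area = h_img * w_img
    log_lo, log_hi = math.log(cfg.aspect_range[0]), math.log(cfg.aspect_range[1])
    for _ in range(10):
        frac = rng.uniform(*cfg.scale_range)
        target_area = frac * area
        ratio = math.exp(rng.uniform(log_lo, log_hi))  # width / height
        ch = math.ceil(math.sqrt(target_area / ratio))
        cw = math.ceil(target_area / ch)
        if 0 < cw <= w_img and 0 < ch <= h_img:
            top = int(rng.integers(0, h_img - ch + 1))
            left = int(rng.integers(0, w_img - cw + 1))
            return top, left, ch, cw
    # fallback: clamp aspect, centre the crop
    in_ratio = w_img / h_img
    if in_ratio < cfg.aspect_range[0]:
        cw = w_img
        ch = int(round(cw / cfg.aspect_range[0]))
    elif in_ratio > cfg.aspect_range[1]:
        ch = h_img
        cw = int(round(ch * cfg.aspect_range[1]))
    else:
        cw, ch = w_img, h_img
    return (h_img - ch) // 2, (w_img - cw) // 2, ch, cw


def sample_jitter_factors(
    cfg: AugmentationConfig, rng: np.random.Generator
) -> tuple[float, float, float]:
    """Independent Uniform(1−j, 1+j) factors for brightness/contrast/saturation."""
    j = cfg.jitter_fraction
    b, c, s = rng.uniform(1 - j, 1 + j, size=3)
    return float(b), float(c), float(s)


def color_jitter(image: np.ndarray, factors: tuple[float, float, float]) -> np.ndarray:
    """Scale brightness, contrast and saturation by the given factors.

    Brightness multiplies every pixel; contrast interpolates about the
    mean luminance; saturation interpolates with the grayscale image
    (the standard colour-jitter construction, linear in pixel values).
    """
    pil = _as_pil(image)
    pil = ImageEnhance.Brightness(pil).enhance(factors[0])
    pil = ImageEnhance.Contrast(pil).enhance(factors[1])
    pil = ImageEnhance.Color(pil).enhance(factors[2])
    return np.asarray(pil)


def advanced_augment(
    image: np.ndarray,
    cfg: AugmentationConfig,
    rng: np.random.Generator,
    *,
    rotation: int | None = None,
    flip: bool | None = None,
) -> np.ndarray:
    """Random-resized-crop training transform with colour jitter."""
    top, left, ch, cw = sample_crop_geometry(image.shape[:2], cfg, rng)
    crop = image[top : top + ch, left : left + cw]
    t = cfg.target_size
    resized = np.asarray(_as_pil(np.ascontiguousarray(crop)).resize((t, t), Image.BILINEAR))
    out = _rotate_flip(resized, cfg, rng, rotation, flip)
    if cfg.jitter_fraction > 0:
        out = color_jitter(out, sample_jitter_factors(cfg, rng))
    return out


def augment(
    image: np.ndarray, cfg: AugmentationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Dispatch on ``cfg.strategy``."""
    if cfg.strategy == "base":
        return base_augment(image, cfg, rng)
    return advanced_augment(image, cfg, rng)


def normalize(
    image: np.ndarray, stats: NormalizationStats = NormalizationStats()
) -> np.ndarray:
    """Scale to [0, 1] then standardize per channel: (x − mean) / sd."""
    x = image.astype(np.float64) / 255.0
    mean = np.asarray(stats.mean)
    sd = np.asarray(stats.sd)
    return (x - mean) / sd


def denormalize(array: np.ndarray, stats: NormalizationStats = NormalizationStats()) -> np.ndarray:
    """Algebraic inverse of :func:`normalize` (back to uint8, rounded)."""
    x = (array * np.asarray(stats.sd) + np.asarray(stats.mean)) * 255.0
    return np.clip(np.round(x), 0, 255).astype(np.uint8)


def center_crop(image: np.ndarray, size: int) -> np.ndarray:
    h, w = image.shape[:2]
    if h < size or w < size:
        raise ValueError(f"image ({w}x{h}) smaller than crop size {size}")
    top = (h - size) // 2
    left = (w - size) // 2
    return np.ascontiguousarray(image[top : top + size, left : left + size])


def ten_crops(image: np.ndarray, size: int) -> list[np.ndarray]:
    """Centre + four corner crops and their horizontal flips.

    Order matches :data:`CROP_IDS`:
    [center, TL, TR, BL, BR, center_f, TL_f, TR_f, BL_f, BR_f].
    """
    h, w = image.shape[:2]
    if h < size or w < size:
        raise ValueError(f"image ({w}x{h}) smaller than crop size {size}")
    base = [
        center_crop(image, size),
        image[:size, :size],                # TL
        image[:size, w - size :],           # TR
        image[h - size :, :size],           # BL
        image[h - size :, w - size :],      # BR
    ]
    flips = [np.fliplr(c) for c in base]
    return [np.ascontiguousarray(c) for c in base + flips]


def test_time_crops(
    image: np.ndarray, cfg: AugmentationConfig, strategy: str
) -> list[np.ndarray]:
    """Deterministic evaluation crops: resize shorter edge, then crop(s)."""
    resized = resize_shorter_edge(image, cfg.resize_edge)
    if strategy == "center_crop":
        return [center_crop(resized, cfg.target_size)]
    if strategy == "ten_crop":
        return ten_crops(resized, cfg.target_size)
    raise ValueError(f"unknown test strategy {strategy!r}")
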