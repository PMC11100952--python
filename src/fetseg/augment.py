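"""The nine-fold training-set augmentation pipeline.

Each input image/label pair is expanded into exactly nine variants, one per
named strategy (so a training split of 2,299 pairs becomes 20,691):

1. ``Rz``            resize to the target size, nothing else;
2. ``RC+Rz``         random 128x128 crop of the resized image, resized back;
3. ``VF+Rz``         vertical flip, probability 0.3;
4. ``HF+Rz``         horizontal flip, probability 0.3;
5. ``ROT+Rz``        rotation within +/-30 degrees, probability 0.3;
6. ``CMB``           random crop, vertical flip, horizontal flip, rotation
                     chained with the same constants;
7. ``RRC+Rz``        random upscale by a factor in [1.2, 1.4], then crop
                     back to the target size;
8. ``PAD+RC+Rz``     reflective padding (32 px per side) then random crop;
9. ``RB+ET+GN+GB``   brightness/contrast jitter, elastic deformation
                     (alpha=1, sigma=50), Gaussian noise (variance 10-50 on
                     the 8-bit scale) and Gaussian blur (kernel 3-7), each
                     applied with probability 0.5.

Geometric transforms act identically on image and label map; labels are
always resampled nearest-neighbour and geometric border fill is background
(class 0). Intensity transforms (RB, GN, GB) leave the label map untouched.
Probabilistic sub-transforms may no-op, but every strategy still emits its
(possibly only-resized) output, so the 9x count always holds. Validation
data must never pass through this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
from scipy import ndimage
from skimage import transform as sktransform

from .data_model import ImageSample

__all__ = [
    "AugmentationStrategy",
    "STRATEGY_NAMES",
    "build_strategies",
    "apply_strategy",
    "augment_dataset",
    "iter_augment",
]

STRATEGY_NAMES = (
    "Rz",
    "RC+Rz",
    "VF+Rz",
    "HF+Rz",
    "ROT+Rz",
    "CMB",
    "RRC+Rz",
    "PAD+RC+Rz",
    "RB+ET+GN+GB",
)


@dataclass(frozen=True)
class AugmentationStrategy:
    name: str
    parameters: dict = field(default_factory=dict)


def build_strategies(size: int = 256) -> list[AugmentationStrategy]:
    """The nine strategies in pipeline order with their constants.

    ``size`` is the common output side; the crop (128 at 256) and pad
    (32 at 256) constants scale proportionally for smaller targets.
    """
    crop = max(2, size // 2)
    pad = max(1, size // 8)
    common = {"size": size}
    return [
        AugmentationStrategy("Rz", {**common}),
        AugmentationStrategy("RC+Rz", {**common, "crop": crop}),
        AugmentationStrategy("VF+Rz", {**common, "p_flip": 0.3}),
        AugmentationStrategy("HF+Rz", {**common, "p_flip": 0.3}),
        AugmentationStrategy("ROT+Rz", {**common, "limit_deg": 30.0, "p_rot": 0.3}),
        AugmentationStrategy(
            "CMB", {**common, "crop": crop, "p_flip": 0.3, "limit_deg": 30.0, "p_rot": 0.3}
        ),
        AugmentationStrategy("RRC+Rz", {**common, "scale": (1.2, 1.4)}),
        AugmentationStrategy("PAD+RC+Rz", {**common, "pad": pad}),
        AugmentationStrategy(
            "RB+ET+GN+GB",
            {
                **common,
                "p": 0.5,
                "brightness_limit": 0.2,
                "contrast_limit": 0.2,
                "elastic_alpha": 1.0,
                "elastic_sigma": 50.0,
                "noise_var": (10.0, 50.0),
                "blur_limit": (3, 7),
            },
        ),
    ]


def _resize_pair(image, mask, shape):
    if image.shape == tuple(shape):
        return image, mask
    img = sktransform.resize(image, shape, order=1, preserve_range=True, anti_aliasing=True)
    msk = sktransform.resize(
        mask.astype(np.float64), shape, order=0, preserve_range=True, anti_aliasing=False
    )
    return img, np.round(msk).astype(np.int64)


def _random_crop(image, mask, crop, rng):
    h, w = image.shape
    if h < crop or w < crop:
        raise ValueError(f"input {image.shape} smaller than crop {crop}")
    y0 = int(rng.integers(0, h - crop + 1))
    x0 = int(rng.integers(0, w - crop + 1))
    return image[y0 : y0 + crop, x0 : x0 + crop], mask[y0 : y0 + crop, x0 : x0 + crop]


def _rotate_pair(image, mask, angle):
    img = sktransform.rotate(image, angle, order=1, mode="constant", cval=0.0, preserve_range=True)
    msk = sktransform.rotate(
        mask.astype(np.float64), angle, order=0, mode="constant", cval=0.0, preserve_range=True
    )
    return img, np.round(msk).astype(np.int64)


def _elastic_pair(image, mask, alpha, sigma, rng):
    h, w = image.shape
    dy = ndimage.gaussian_filter(rng.uniform(-1, 1, (h, w)), sigma, mode="reflect") * alpha
    dx = ndimage.gaussian_filter(rng.uniform(-1, 1, (h, w)), sigma, mode="reflect") * alpha
    yy, xx = np.indices((h, w), dtype=np.float64)
    coords = np.stack([yy + dy, xx + dx])
    img = ndimage.map_coordinates(image, coords, order=1, mode="reflect")
    msk = ndimage.map_coordinates(mask, coords, order=0, mode="nearest")
    return img, msk.astype(np.int64)


def apply_strategy(sample: ImageSample, strategy: AugmentationStrategy, seed: int) -> ImageSample:
    """Apply one named strategy; bit-deterministic given ``seed``."""
    rng = np.random.default_rng(seed)
    p = strategy.parameters
    size = p.get("size", 256)
    img, msk = _resize_pair(sample.image, sample.label_map, (size, size))
    name = strategy.name

    if name in ("RC+Rz", "CMB"):
        img, msk = _random_crop(img, msk, p["crop"], rng)
        img, msk = _resize_pair(img, msk, (size, size))
    if name in ("VF+Rz", "CMB"):
        if rng.random() < p["p_flip"]:
            img, msk = img[::-1].copy(), msk[::-1].copy()
    if name in ("HF+Rz", "CMB"):
        if rng.random() < p["p_flip"]:
            img, msk = img[:, ::-1].copy(), msk[:, ::-1].copy()
    if name in ("ROT+Rz", "CMB"):
        if rng.random() < p["p_rot"]:
            angle = rng.uniform(-p["limit_deg"], p["limit_deg"])
            img, msk = _rotate_pair(img, msk, angle)
    if name == "RRC+Rz":
        scale = rng.uniform(*p["scale"])
        big = int(round(size * scale))
        img, msk = _resize_pair(img, msk, (big, big))
        img, msk = _random_crop(img, msk, size, rng)
    if name == "PAD+RC+Rz":
        pad = p["pad"]
        img = np.pad(img, pad, mode="reflect")
        msk = np.pad(msk, pad, mode="reflect")
        img, msk = _random_crop(img, msk, size, rng)
    if name == "RB+ET+GN+GB":
        if rng.random() < p["p"]:  # brightness / contrast
            bright = rng.uniform(-p["brightness_limit"], p["brightness_limit"])
            contrast = rng.uniform(-p["contrast_limit"], p["contrast_limit"])
            img = img * (1.0 + contrast) + bright
        if rng.random() < p["p"]:  # elastic
            img, msk = _elastic_pair(img, msk, p["elastic_alpha"], p["elastic_sigma"], rng)
        if rng.random() < p["p"]:  # gaussian noise (variance on the 0-255 scale)
            var = rng.uniform(*p["noise_var"])
            img = img + rng.normal(0.0, np.sqrt(var) / 255.0, img.shape)
        if rng.random() < p["p"]:  # gaussian blur
            lo, hi = p["blur_limit"]
            ksize = int(rng.choice(np.arange(lo, hi + 1, 2)))
            sigma = 0.3 * ((ksize - 1) * 0.5 - 1) + 0.8
            img = ndimage.gaussian_filter(img, sigma)

    img = np.clip(img, 0.0, 1.0)
    return ImageSample(img, msk, f"{sample.identifier}__{name}")


def iter_augment(samples: Iterable[ImageSample], seed: int, size: int = 256) -> Iterator[ImageSample]:
    """Lazily yield the 9 variants of each sample (memory-bounded)."""
    strategies = build_strategies(size)
    for i, sample in enumerate(samples):
        for j, strat in enumerate(strategies):
            child = int(
                np.random.SeedSequence([seed & 0x7FFFFFFF, i, j]).generate_state(1)[0]
            )
            yield apply_strategy(sample, strat, child)


def augment_dataset(samples: list[ImageSample], seed: int, size: int = 256) -> list[ImageSample]:
    """Materialised 9x expansion; output count is exactly ``9 * len(samples)``."""
    return list(iter_augment(samples, seed, size))
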