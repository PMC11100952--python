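"""Seeded fetal-head phantom generator and dataset splitter.

Real trans-thalamic / trans-ventricular ultrasound planes show one dominant
bright elliptical brain region on a dark background, with two tiny internal
structures — the cavum septum pellucidum (CSP) near the midline and the
lateral ventricles (LV) laterally — and heavy multiplicative speckle. The
phantom emulates exactly that class geometry (and the resulting extreme
class imbalance) so that weighting, losses, prompt boxes and metrics can be
exercised without any real data: an axis-aligned bright ellipse (class 1),
a small midline rectangle (class 2, CSP), a small lateral rectangle
(class 3, LV), multiplicative Gaussian speckle over everything. In
first-trimester planes CSP and LV are not yet visible; a configurable
fraction of generated samples omits them to mirror that.

The splitter reproduces the 60/20/20 train/val/test convention with
floor-then-remainder rounding (the remainder goes to test), which maps
3,832 images onto the (2299, 766, 767) triple.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .data_model import ImageSample

__all__ = [
    "PhantomParams",
    "SplitFractions",
    "GenerationError",
    "generate_phantom",
    "generate_dataset",
    "split_dataset",
    "assign_split",
]


class GenerationError(RuntimeError):
    """A structure could not be placed inside the brain ellipse."""


# per-class base echogenicity on [0,1]; fluid-filled CSP/LV are hypoechoic
_INTENSITY = (0.12, 0.55, 0.30, 0.22)


@dataclass(frozen=True)
class PhantomParams:
    """Geometry and noise settings; pixel ranges default to ~256-scale
    proportions and scale linearly with the requested size."""

    height: int = 256
    width: int = 256
    brain_axes_range: tuple[tuple[int, int], tuple[int, int]] | None = None
    csp_size_range: tuple[int, int] | None = None
    lv_size_range: tuple[int, int] | None = None
    include_csp: bool = True
    include_lv: bool = True
    speckle_variance: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("height and width must be positive")
        if self.speckle_variance < 0:
            raise ValueError("speckle_variance must be >= 0")

    def _scale(self) -> float:
        return min(self.height, self.width) / 256.0

    def resolved_brain_axes(self) -> tuple[tuple[int, int], tuple[int, int]]:
        if self.brain_axes_range is not None:
            return self.brain_axes_range
        s = self._scale()
        return (
            (max(4, round(56 * s)), max(5, round(88 * s))),  # x semi-axis
            (max(3, round(44 * s)), max(4, round(68 * s))),  # y semi-axis
        )

    def resolved_csp_size(self) -> tuple[int, int]:
        if self.csp_size_range is not None:
            return self.csp_size_range
        s = self._scale()
        return (max(2, round(5 * s)), max(2, round(9 * s)))

    def resolved_lv_size(self) -> tuple[int, int]:
        if self.lv_size_range is not None:
            return self.lv_size_range
        s = self._scale()
        return (max(2, round(7 * s)), max(3, round(12 * s)))


@dataclass(frozen=True)
class SplitFractions:
    train: float = 0.6
    val: float = 0.2
    test: float = 0.2

    def __post_init__(self) -> None:
        for f in (self.train, self.val, self.test):
            if not 0.0 < f < 1.0:
                raise ValueError("each split fraction must lie in (0, 1)")
        if abs(self.train + self.val + self.test - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def _place_rect(
    rng: np.random.Generator,
    ellipse: tuple[float, float, float, float],
    size_range: tuple[int, int],
    x_band: tuple[float, float],
    occupied: np.ndarray,
) -> tuple[slice, slice]:
    """Place an axis-aligned rectangle fully inside the (shrunken) ellipse,
    with its centre's x-offset drawn from ``x_band`` (in units of the
    x semi-axis), avoiding already-occupied pixels."""
    cy, cx, a, b = ellipse  # a: x semi-axis, b: y semi-axis
    lo, hi = size_range
    for _ in range(200):
        w = int(rng.integers(lo, hi + 1))
        h = int(rng.integers(lo, hi + 1))
        fx = rng.uniform(*x_band) * (1 if rng.random() < 0.5 else -1)
        fy = rng.uniform(-0.35, 0.35)
        rcx = cx + fx * a
        rcy = cy + fy * b
        y0, x0 = int(round(rcy - h / 2)), int(round(rcx - w / 2))
        y1, x1 = y0 + h, x0 + w
        corners = np.array([[y0, x0], [y0, x1 - 1], [y1 - 1, x0], [y1 - 1, x1 - 1]])
        inside = ((corners[:, 1] - cx) / a) ** 2 + ((corners[:, 0] - cy) / b) ** 2
        if np.any(inside > 0.7):
            continue
        sl = (slice(y0, y1), slice(x0, x1))
        if occupied[sl].any():
            continue
        return sl
    raise GenerationError("could not place rectangle inside brain ellipse")


def generate_phantom(params: PhantomParams, index: int) -> ImageSample:
    """Generate one phantom sample, bit-deterministic in ``(seed, index)``."""
    h, w = params.height, params.width
    rng = np.random.default_rng(np.random.SeedSequence([params.seed & 0x7FFFFFFF, index]))

    (a_lo, a_hi), (b_lo, b_hi) = params.resolved_brain_axes()
    a = float(rng.integers(a_lo, a_hi + 1))
    b = float(rng.integers(b_lo, b_hi + 1))
    cy = h / 2 + rng.uniform(-0.04, 0.04) * h
    cx = w / 2 + rng.uniform(-0.04, 0.04) * w

    yy, xx = np.indices((h, w))
    label = np.zeros((h, w), dtype=np.int64)
    brain = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
    label[brain] = 1

    occupied = np.zeros((h, w), dtype=bool)
    if params.include_csp:
        sl = _place_rect(rng, (cy, cx, a, b), params.resolved_csp_size(), (0.0, 0.12), occupied)
        label[sl] = 2
        occupied[sl] = True
    if params.include_lv:
        sl = _place_rect(rng, (cy, cx, a, b), params.resolved_lv_size(), (0.3, 0.55), occupied)
        label[sl] = 3

    image = np.take(np.asarray(_INTENSITY), label).astype(np.float64)
    image = ndimage.gaussian_filter(image, sigma=1.0)
    speckle = 1.0 + np.sqrt(params.speckle_variance) * rng.standard_normal((h, w))
    image = np.clip(image * speckle, 0.0, 1.0)

    counts = np.bincount(label.ravel(), minlength=4)
    if not (counts[0] > counts[1] > max(counts[2], counts[3])):
        raise GenerationError("class-count ordering violated")  # pragma: no cover
    return ImageSample(image, label, f"phantom_{params.seed & 0x7FFFFFFF:d}_{index:05d}")


def generate_dataset(
    n: int, params: PhantomParams, no_structures_frac: float = 0.2
) -> list[ImageSample]:
    """Generate ``n`` phantoms; a ``no_structures_frac`` share of them are
    first-trimester-like planes without CSP/LV (chosen deterministically
    per index under the run seed)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    samples = []
    for i in range(n):
        plane_rng = np.random.default_rng(
            np.random.SeedSequence([params.seed & 0x7FFFFFFF, i, 0xA])
        )
        p = params
        if params.include_csp and params.include_lv and plane_rng.random() < no_structures_frac:
            p = replace(params, include_csp=False, include_lv=False)
        samples.append(generate_phantom(p, i))
    return samples


def split_dataset(n: int, fractions: SplitFractions = SplitFractions()) -> tuple[int, int, int]:
    """Floor-then-remainder 3-way split: train and val take the floors of
    their fractions, test absorbs the remainder (3832 -> 2299/766/767)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    train = int(np.floor(n * fractions.train))
    val = int(np.floor(n * fractions.val))
    return train, val, n - train - val


def assign_split(
    stems: list[str], fractions: SplitFractions = SplitFractions(), seed: int = 0
) -> dict[str, list[str]]:
    """Deterministic shuffled assignment of stems to train/val/test."""
    train_n, val_n, _ = split_dataset(len(stems), fractions)
    order = list(stems)
    np.random.default_rng(seed & 0x7FFFFFFF).shuffle(order)
    return {
        "train": sorted(order[:train_n]),
        "val": sorted(order[train_n : train_n + val_n]),
        "test": sorted(order[train_n + val_n :]),
    }
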