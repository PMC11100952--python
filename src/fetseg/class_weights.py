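"""Inverse-frequency class weights with min-max range smoothing.

The four fetal-head classes are wildly imbalanced: background and brain
dominate the pixel budget while CSP and LV occupy a few dozen pixels each.
Weights are derived in three steps from pixel tallies over a mask
collection:

1. count pixels per class (zero counts are replaced by one so the inverse
   exists);
2. raw weight per class = total pixels / class count, then normalised to
   sum to one;
3. min-max rescale of the normalised weights into ``[min_weight,
   max_weight]``, so the rarest class lands exactly on ``max_weight`` and
   the most frequent on ``min_weight``.

On realistic data the result has the characteristic shape
small/small/large/medium, e.g. ``[0.1, 0.1, 0.9, 0.7]`` for
background/brain/CSP/LV. When all classes are equally frequent the rescale
is degenerate and every class gets the midpoint of the range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import decode_argmax

__all__ = ["ClassCounts", "ClassWeights", "count_classes", "compute_weights"]


@dataclass(frozen=True)
class ClassCounts:
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", tuple(int(c) for c in self.counts))


@dataclass(frozen=True)
class ClassWeights:
    weights: tuple[float, ...]
    min_weight: float = 0.1
    max_weight: float = 0.9

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", tuple(float(w) for w in self.weights))

    def __len__(self) -> int:
        return len(self.weights)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=np.float64)

    @classmethod
    def uniform(cls, n_classes: int, value: float = 1.0) -> "ClassWeights":
        return cls((value,) * n_classes, min_weight=value, max_weight=value)


def count_classes(masks, n_classes: int = 4) -> ClassCounts:
    """Tally pixels per class over a collection of label maps or one-hot
    masks; zero tallies are replaced by one (so inverse frequency is
    defined for classes absent from the collection)."""
    counts = np.zeros(n_classes, dtype=np.int64)
    n_seen = 0
    for mask in masks:
        mask = np.asarray(mask)
        if mask.ndim == 3:  # one-hot C x H x W
            mask = decode_argmax(mask)
        binc = np.bincount(mask.ravel(), minlength=n_classes)
        if len(binc) > n_classes:
            raise ValueError(f"mask contains label >= {n_classes}")
        counts += binc
        n_seen += 1
    if n_seen == 0:
        raise ValueError("empty mask collection")
    counts[counts == 0] = 1
    return ClassCounts(tuple(counts))


def compute_weights(
    counts: ClassCounts, min_weight: float = 0.1, max_weight: float = 0.9
) -> ClassWeights:
    """Inverse-frequency weights rescaled into ``[min_weight, max_weight]``.

    Equal counts (degenerate rescale) map every class to the range
    midpoint.
    """
    if min_weight >= max_weight:
        raise ValueError("min_weight must be < max_weight")
    arr = np.asarray(counts.counts, dtype=np.float64)
    if np.any(arr <= 0):
        raise ValueError("counts must be >= 1; apply zero-handling first")
    raw = arr.sum() / arr
    norm = raw / raw.sum()
    lo, hi = norm.min(), norm.max()
    if hi - lo < 1e-300:
        w = np.full_like(norm, (min_weight + max_weight) / 2.0)
    else:
        w = (norm - lo) / (hi - lo) * (max_weight - min_weight) + min_weight
    return ClassWeights(tuple(w), min_weight, max_weight)
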