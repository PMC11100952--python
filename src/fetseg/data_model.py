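"""Core label conventions and conversions.

A segmentation problem over ``C`` classes is carried through the toolkit in
three interchangeable per-pixel representations:

``LabelMap``
    an ``H x W`` integer grid, each entry the class index of that pixel;
``OneHotMask``
    its ``C x H x W`` binary expansion (exactly one active channel per pixel);
``ProbabilityMap``
    a ``C x H x W`` real grid of per-class probabilities from a segmenter.

All grids are channel-first, row-major, 0-based; ``y`` indexes rows
(downward) and ``x`` columns (rightward). Index 0 is always background.
The default schema is the 4-class fetal-head layout: background, fetal
brain, cavum septum pellucidum (CSP) and lateral ventricles (LV).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LabelSchema",
    "ImageSample",
    "InvalidLabelError",
    "DEFAULT_SCHEMA",
    "encode_one_hot",
    "decode_argmax",
]


class InvalidLabelError(ValueError):
    """A label map contains a class index outside ``[0, n_classes)``."""


@dataclass(frozen=True)
class LabelSchema:
    """Ordered class names; index 0 must be background."""

    class_names: tuple[str, ...] = ("background", "brain", "CSP", "LV")

    def __post_init__(self) -> None:
        if len(self.class_names) < 2:
            raise ValueError("a schema needs at least background + 1 class")
        if len(set(self.class_names)) != len(self.class_names):
            raise ValueError("class names must be unique")
        object.__setattr__(self, "class_names", tuple(self.class_names))

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


DEFAULT_SCHEMA = LabelSchema()


@dataclass
class ImageSample:
    """A grayscale image paired with its per-pixel label map.

    ``image`` is float in [0, 1], shape ``H x W``; ``label_map`` is an
    integer grid of the same shape.
    """

    image: np.ndarray
    label_map: np.ndarray
    identifier: str = ""

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float64)
        self.label_map = np.asarray(self.label_map)
        if self.image.ndim != 2:
            raise ValueError(f"image must be 2-D, got shape {self.image.shape}")
        if self.image.shape != self.label_map.shape:
            raise ValueError(
                f"image {self.image.shape} and label map "
                f"{self.label_map.shape} shapes differ"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape


def _validate_label_map(label_map: np.ndarray) -> np.ndarray:
    arr = np.asarray(label_map)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"label map must be non-empty 2-D, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.array_equal(arr, arr.astype(np.int64)):
            raise InvalidLabelError("label map entries must be integers")
        arr = arr.astype(np.int64)
    if arr.min() < 0:
        raise InvalidLabelError(f"negative label {int(arr.min())}")
    return arr


def encode_one_hot(label_map: np.ndarray, schema: LabelSchema = DEFAULT_SCHEMA) -> np.ndarray:
    """Expand an ``H x W`` label map into a ``C x H x W`` one-hot mask.

    Channel ``c`` is 1 exactly where ``label_map == c``; every pixel is
    active in exactly one channel.

    Raises
    ------
    InvalidLabelError
        if any entry is >= ``schema.n_classes``.
    """
    arr = _validate_label_map(label_map)
    c = schema.n_classes
    if arr.max() >= c:
        raise InvalidLabelError(
            f"label {int(arr.max())} out of range for {c} classes"
        )
    one_hot = np.zeros((c, *arr.shape), dtype=np.uint8)
    # advanced indexing: one write per pixel
    yy, xx = np.indices(arr.shape)
    one_hot[arr, yy, xx] = 1
    return one_hot


def decode_argmax(prob: np.ndarray) -> np.ndarray:
    """Collapse a ``C x H x W`` probability (or one-hot) map to labels.

    Each pixel takes the index of its maximal channel; ties break to the
    lowest class index (numpy argmax convention), so background wins exact
    ties with foreground classes.
    """
    prob = np.asarray(prob)
    if prob.ndim != 3 or prob.shape[0] < 2:
        raise ValueError(f"expected C x H x W with C >= 2, got {prob.shape}")
    if prob.shape[1] == 0 or prob.shape[2] == 0:
        raise ValueError("empty grid")
    return np.argmax(prob, axis=0).astype(np.int64)
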