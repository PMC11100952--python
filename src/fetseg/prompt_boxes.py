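"""Per-class prompt bounding boxes from segmentation masks.

A promptable segmenter is localised with one rectangle per class, derived
from the one-hot mask: threshold the class channel, take the min/max of
the activated row and column indices, then expand the box symmetrically
outward by ``offset`` pixels, clamping at the image bounds. Classes with
no activated pixel get the sentinel ``[0, 0, 0, 0]``; the result always
contains every class index. Boxes are ``[x_min, y_min, x_max, y_max]``
with 0-based inclusive pixel indices.

Larger offsets yield looser prompts; sweeping offset over {0, 10, 20} is
the standard prompt-size ablation (segmentation quality degrades as the
prompt loosens).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import LabelSchema, DEFAULT_SCHEMA, encode_one_hot

__all__ = ["BoundingBox", "PromptConfig", "derive_boxes", "boxes_from_label_map"]


@dataclass(frozen=True)
class BoundingBox:
    x_min: int
    y_min: int
    x_max: int
    y_max: int

    def __post_init__(self) -> None:
        if not self.is_sentinel and (self.x_min > self.x_max or self.y_min > self.y_max):
            raise ValueError(f"degenerate box {self.as_list()}")

    @property
    def is_sentinel(self) -> bool:
        return (self.x_min, self.y_min, self.x_max, self.y_max) == (0, 0, 0, 0)

    def as_list(self) -> list[int]:
        return [self.x_min, self.y_min, self.x_max, self.y_max]

    def contains(self, other: "BoundingBox") -> bool:
        return (
            self.x_min <= other.x_min
            and self.y_min <= other.y_min
            and self.x_max >= other.x_max
            and self.y_max >= other.y_max
        )


@dataclass(frozen=True)
class PromptConfig:
    threshold: float = 0.5
    offset: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold < 1.0:
            raise ValueError("threshold must lie in [0, 1)")
        if self.offset < 0:
            raise ValueError("offset must be >= 0")


def derive_boxes(
    mask: np.ndarray, config: PromptConfig = PromptConfig(), n_classes: int | None = None
) -> dict[int, BoundingBox]:
    """One box per class from a ``C x H x W`` (one-hot or soft) mask."""
    mask = np.asarray(mask, dtype=np.float64)
    if mask.ndim != 3:
        raise ValueError(f"expected C x H x W mask, got shape {mask.shape}")
    c, h, w = mask.shape
    if n_classes is None:
        n_classes = c
    boxes: dict[int, BoundingBox] = {}
    for i in range(min(c, n_classes)):
        ys, xs = np.nonzero(mask[i] > config.threshold)
        if ys.size == 0:
            continue
        x_min = max(0, int(xs.min()) - config.offset)
        y_min = max(0, int(ys.min()) - config.offset)
        x_max = min(w - 1, int(xs.max()) + config.offset)
        y_max = min(h - 1, int(ys.max()) + config.offset)
        boxes[i] = BoundingBox(x_min, y_min, x_max, y_max)
    for i in range(n_classes):
        if i not in boxes:
            boxes[i] = BoundingBox(0, 0, 0, 0)
    return dict(sorted(boxes.items()))


def boxes_from_label_map(
    label_map: np.ndarray,
    config: PromptConfig = PromptConfig(),
    schema: LabelSchema = DEFAULT_SCHEMA,
) -> dict[int, BoundingBox]:
    """Convenience: one-hot encode then derive boxes."""
    return derive_boxes(encode_one_hot(label_map, schema), config, schema.n_classes)
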