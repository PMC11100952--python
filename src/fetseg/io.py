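"""On-disk dataset layout: paired 8-bit PNGs.

A dataset directory holds ``images/<stem>.png`` (8-bit grayscale) and
``masks/<stem>.png`` (8-bit indexed, pixel value = class index), paired by
filename stem. A small fixed palette makes the index masks viewable.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

from .data_model import ImageSample

__all__ = ["save_sample", "load_sample", "save_dataset", "load_dataset", "list_stems"]

# background, brain, CSP, LV + spare slots
_PALETTE = [
    (0, 0, 0),
    (180, 180, 180),
    (220, 60, 60),
    (60, 100, 220),
    (60, 200, 120),
    (230, 200, 60),
    (200, 60, 200),
    (60, 200, 220),
]


def _mask_to_indexed(label_map: np.ndarray) -> Image.Image:
    img = Image.fromarray(label_map.astype(np.uint8), mode="P")
    flat = [v for rgb in _PALETTE for v in rgb]
    flat += [0] * (768 - len(flat))
    img.putpalette(flat)
    return img


def save_sample(sample: ImageSample, root: Path | str) -> None:
    root = Path(root)
    (root / "images").mkdir(parents=True, exist_ok=True)
    (root / "masks").mkdir(parents=True, exist_ok=True)
    img8 = np.clip(np.round(sample.image * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(img8, mode="L").save(root / "images" / f"{sample.identifier}.png")
    _mask_to_indexed(sample.label_map).save(root / "masks" / f"{sample.identifier}.png")


def load_sample(root: Path | str, stem: str) -> ImageSample:
    root = Path(root)
    img = np.asarray(Image.open(root / "images" / f"{stem}.png").convert("L"))
    mask = np.asarray(Image.open(root / "masks" / f"{stem}.png"))
    return ImageSample(img.astype(np.float64) / 255.0, mask.astype(np.int64), stem)


def save_dataset(samples, root: Path | str) -> None:
    for s in samples:
        save_sample(s, root)


def list_stems(root: Path | str) -> list[str]:
    root = Path(root)
    return sorted(p.stem for p in (root / "images").glob("*.png"))


def load_dataset(root: Path | str, stems=None) -> list[ImageSample]:
    if stems is None:
        stems = list_stems(root)
    return [load_sample(root, s) for s in stems]
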