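"""Per-class segmentation metrics: DSC, Hausdorff and average surface distance.

For each class ``c`` the predicted and truth label maps induce pixel sets
``A`` (prediction) and ``B`` (truth):

* ``DSC(A, B) = 2|A n B| / (|A| + |B|)`` — overlap, 1 is perfect;
* ``HD(A, B)`` — the symmetric Hausdorff distance between the two sets of
  *border* points under Euclidean pixel distance (worst-case boundary
  error);
* ``ASD(A, B)`` — the directed mean distance from each predicted border
  point to its nearest truth border point (a symmetric variant is
  available).

A border point is a class pixel with at least one 4-neighbour outside the
class, or one lying on the image edge. Distances are in pixel units; no
physical spacing is applied.

Empty-set conventions: if both classes are empty the prediction is deemed
perfect (DSC 1, HD 0, ASD 0); if exactly one is empty the miss is scored
DSC 0 and HD = ASD = the image diagonal (a finite, monotone-safe penalty).

``evaluate`` reports the per-class triples for *all* classes, background
included, plus their unweighted arithmetic means — the aggregation
convention used throughout the report tables.
"""

from __future__ import annotations

import csv
import io as _io
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .data_model import LabelSchema, DEFAULT_SCHEMA

__all__ = [
    "EvalReport",
    "dsc",
    "hausdorff",
    "asd",
    "evaluate",
    "aggregate_mean",
    "boundary_points",
    "report_table",
    "parse_report_table",
]

_CROSS = ndimage.generate_binary_structure(2, 1)  # 4-connectivity


def _class_sets(pred, truth, class_index):
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    return pred == class_index, truth == class_index


def dsc(pred: np.ndarray, truth: np.ndarray, class_index: int) -> float:
    """Dice similarity coefficient for one class; both-empty scores 1."""
    a, b = _class_sets(pred, truth, class_index)
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def boundary_points(region: np.ndarray) -> np.ndarray:
    """(y, x) coordinates of the region's border points (4-neighbour rule;
    image-edge pixels of the region are border)."""
    region = np.asarray(region, dtype=bool)
    if not region.any():
        return np.empty((0, 2), dtype=np.int64)
    interior = ndimage.binary_erosion(region, structure=_CROSS, border_value=0)
    return np.argwhere(region & ~interior)


def _diagonal(shape) -> float:
    return float(np.hypot(shape[0], shape[1]))


def hausdorff(pred: np.ndarray, truth: np.ndarray, class_index: int) -> float:
    """Symmetric Hausdorff distance between the class border point sets."""
    a, b = _class_sets(pred, truth, class_index)
    pa, pb = boundary_points(a), boundary_points(b)
    if len(pa) == 0 and len(pb) == 0:
        return 0.0
    if len(pa) == 0 or len(pb) == 0:
        return _diagonal(np.asarray(pred).shape)
    d_ab = cKDTree(pb).query(pa)[0].max()
    d_ba = cKDTree(pa).query(pb)[0].max()
    return float(max(d_ab, d_ba))


def asd(
    pred: np.ndarray, truth: np.ndarray, class_index: int, symmetric: bool = False
) -> float:
    """Average surface distance from predicted to truth border points
    (directed by default; ``symmetric=True`` pools both directions)."""
    a, b = _class_sets(pred, truth, class_index)
    pa, pb = boundary_points(a), boundary_points(b)
    if len(pa) == 0 and len(pb) == 0:
        return 0.0
    if len(pa) == 0 or len(pb) == 0:
        return _diagonal(np.asarray(pred).shape)
    d_ab = cKDTree(pb).query(pa)[0]
    if not symmetric:
        return float(d_ab.mean())
    d_ba = cKDTree(pa).query(pb)[0]
    return float((d_ab.sum() + d_ba.sum()) / (len(pa) + len(pb)))


def aggregate_mean(values) -> float:
    """Unweighted arithmetic mean over classes (background included)."""
    values = list(values)
    if not values:
        raise ValueError("nothing to aggregate")
    return float(np.mean(values))


@dataclass(frozen=True)
class EvalReport:
    """Per-class (dsc, hd, asd) triples plus their unweighted means."""

    per_class: dict[str, tuple[float, float, float]]

    @property
    def mean(self) -> tuple[float, float, float]:
        triples = list(self.per_class.values())
        return tuple(aggregate_mean(t[i] for t in triples) for i in range(3))

    @property
    def mean_dsc(self) -> float:
        return self.mean[0]


def evaluate(
    pred: np.ndarray,
    truth: np.ndarray,
    schema: LabelSchema = DEFAULT_SCHEMA,
    symmetric_asd: bool = False,
) -> EvalReport:
    """Per-class and mean DSC/HD/ASD between two label maps."""
    per_class = {}
    for c, name in enumerate(schema.class_names):
        per_class[name] = (
            dsc(pred, truth, c),
            hausdorff(pred, truth, c),
            asd(pred, truth, c, symmetric=symmetric_asd),
        )
    return EvalReport(per_class)


def _round5(x: float) -> float:
    return round(float(x), 5)  # banker's rounding to 5 decimals


def report_table(reports: dict[str, EvalReport]) -> str:
    """CSV with one row per model: per-class and mean DSC/HD/ASD, rounded
    half-even to 5 decimals."""
    if not reports:
        raise ValueError("empty report map")
    schemas = [tuple(r.per_class.keys()) for r in reports.values()]
    if len(set(schemas)) != 1:
        raise ValueError("inconsistent class schemas across reports")
    classes = list(schemas[0]) + ["mean"]
    header = ["model"] + [f"{cls}_{m}" for cls in classes for m in ("dsc", "hd", "asd")]
    buf = _io.StringIO()
    writer = csv.writer(buf)
    writer.writerow(header)
    for model, rep in reports.items():
        cells = []
        for cls in schemas[0]:
            cells.extend(_round5(v) for v in rep.per_class[cls])
        cells.extend(_round5(v) for v in rep.mean)
        writer.writerow([model] + cells)
    return buf.getvalue()


def parse_report_table(text: str) -> dict[str, dict[str, tuple[float, float, float]]]:
    """Inverse of :func:`report_table` (per-class triples only)."""
    reader = csv.reader(_io.StringIO(text))
    header = next(reader)
    classes = [h[: -len("_dsc")] for h in header[1:] if h.endswith("_dsc")]
    out = {}
    for row in reader:
        vals = [float(v) for v in row[1:]]
        out[row[0]] = {
            cls: tuple(vals[3 * i : 3 * i + 3]) for i, cls in enumerate(classes)
        }
    return out
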