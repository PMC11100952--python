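"""Class-weighted Dice and Lovász segmentation losses and their blend.

The combined training objective is

    L = alpha * L_Dice + beta * L_Lovasz          (default alpha = beta = 0.5)

**Weighted Dice.** The soft Dice loss evaluated over all (class, pixel)
entries of the one-hot truth ``y`` and predicted probabilities ``p``, with
each entry weighted by its class weight ``w``:

    L_Dice = 1 - 2 * sum(y * p * w) / sum((y + p) * w)

so a single scalar covers all classes at once and rare classes (large
``w``) dominate both the overlap and the normaliser. A small ``epsilon``
stabilises the ratio when the denominator vanishes. A per-class
Dice-then-weighted-average variant is available via ``dice_mode``.

**Weighted Lovász.** The Lovász extension of the Jaccard (1 - IoU) loss,
computed per class on the error vector ``|y_c - p_c|`` via the
sorted-gradient construction, then combined across classes as the
``w``-weighted mean. At hard {0,1} predictions each class term equals its
Jaccard loss exactly, so the loss optimises IoU directly. A class with no
truth pixels contributes its largest predicted error (which is again
1 - IoU at hard vertices); set ``absent_class_policy='skip'`` to exclude
such classes instead.

Both components live in [0, 1] and vanish exactly when a hard prediction
matches the truth. Analytic gradients with respect to the probabilities
are provided for the numpy training harness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .class_weights import ClassWeights

__all__ = [
    "LossConfig",
    "LossValue",
    "weighted_dice_loss",
    "weighted_lovasz_loss",
    "combined_loss",
    "combined_loss_grad",
]


@dataclass(frozen=True)
class LossConfig:
    class_weights: ClassWeights
    alpha: float = 0.5
    beta: float = 0.5
    epsilon: float = 1e-6
    dice_mode: str = "entry"  # "entry" (literal) or "per_class"
    absent_class_policy: str = "penalty"  # or "skip"

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.dice_mode not in ("entry", "per_class"):
            raise ValueError(f"unknown dice_mode {self.dice_mode!r}")
        if self.absent_class_policy not in ("penalty", "skip"):
            raise ValueError(f"unknown absent_class_policy {self.absent_class_policy!r}")


@dataclass(frozen=True)
class LossValue:
    total: float
    dice_term: float
    lovasz_term: float


def _check_shapes(pred: np.ndarray, truth: np.ndarray, weights: ClassWeights) -> None:
    if pred.shape != truth.shape:
        raise ValueError(f"pred {pred.shape} and truth {truth.shape} shapes differ")
    if pred.ndim != 3:
        raise ValueError("expected C x H x W grids")
    if pred.shape[0] != len(weights):
        raise ValueError(f"{pred.shape[0]} classes but {len(weights)} weights")


def weighted_dice_loss(
    pred: np.ndarray,
    truth: np.ndarray,
    weights: ClassWeights,
    epsilon: float = 1e-6,
    mode: str = "entry",
) -> float:
    """Soft Dice loss with per-entry class weights (``mode='entry'``) or the
    weighted average of per-class Dice losses (``mode='per_class'``)."""
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    _check_shapes(pred, truth, weights)
    w = weights.as_array()
    if mode == "entry":
        wmap = w[:, None, None]
        num = 2.0 * float(np.sum(truth * pred * wmap))
        den = float(np.sum((truth + pred) * wmap))
        return 1.0 - (num + epsilon) / (den + epsilon)
    if mode == "per_class":
        dices = np.empty(len(w))
        for c in range(len(w)):
            num = 2.0 * float(np.sum(truth[c] * pred[c]))
            den = float(np.sum(truth[c] + pred[c]))
            dices[c] = (num + epsilon) / (den + epsilon)
        return float(np.sum(w * (1.0 - dices)) / np.sum(w))
    raise ValueError(f"unknown mode {mode!r}")


def _lovasz_grad(gt_sorted: np.ndarray) -> np.ndarray:
    """Gradient of the Jaccard loss along a descending error ordering."""
    gts = gt_sorted.sum()
    intersection = gts - np.cumsum(gt_sorted)
    union = gts + np.cumsum(1.0 - gt_sorted)
    jaccard = 1.0 - intersection / union
    if len(jaccard) > 1:
        jaccard[1:] = jaccard[1:] - jaccard[:-1]
    return jaccard


def _lovasz_class_terms(pred, truth, policy):
    """Per-class Lovász terms and (for the gradient) the sort machinery."""
    c = pred.shape[0]
    terms, included, grads = [], [], []
    for i in range(c):
        fg = truth[i].ravel().astype(np.float64)
        if fg.sum() == 0 and policy == "skip":
            terms.append(0.0)
            included.append(False)
            grads.append(None)
            continue
        errors = np.abs(fg - pred[i].ravel())
        perm = np.argsort(-errors, kind="stable")
        grad = _lovasz_grad(fg[perm])
        terms.append(float(errors[perm] @ grad))
        included.append(True)
        # d term / d error_j = grad at the rank of j
        g_unsorted = np.empty_like(grad)
        g_unsorted[perm] = grad
        grads.append(g_unsorted)
    return np.asarray(terms), np.asarray(included), grads


def weighted_lovasz_loss(
    pred: np.ndarray,
    truth: np.ndarray,
    weights: ClassWeights,
    absent_class_policy: str = "penalty",
) -> float:
    """Weighted mean over classes of the Lovász-extended Jaccard loss."""
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    _check_shapes(pred, truth, weights)
    w = weights.as_array()
    terms, included, _ = _lovasz_class_terms(pred, truth, absent_class_policy)
    if not included.any():
        return 0.0
    return float(np.sum(w[included] * terms[included]) / np.sum(w[included]))


def combined_loss(pred: np.ndarray, truth: np.ndarray, config: LossConfig) -> LossValue:
    """``alpha * L_Dice + beta * L_Lovasz`` with the component terms."""
    dice = weighted_dice_loss(
        pred, truth, config.class_weights, config.epsilon, config.dice_mode
    )
    lov = weighted_lovasz_loss(
        pred, truth, config.class_weights, config.absent_class_policy
    )
    return LossValue(config.alpha * dice + config.beta * lov, dice, lov)


def combined_loss_grad(
    pred: np.ndarray, truth: np.ndarray, config: LossConfig
) -> tuple[LossValue, np.ndarray]:
    """Loss value and its analytic gradient w.r.t. the probabilities.

    Only the literal entry-weighted Dice mode is differentiated (the mode
    the harness trains with). The Lovász gradient holds the sorting
    permutation fixed, i.e. it is the standard piecewise-linear
    subgradient.
    """
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    w = config.class_weights.as_array()
    _check_shapes(pred, truth, config.class_weights)
    eps = config.epsilon
    wmap = w[:, None, None]

    num = 2.0 * float(np.sum(truth * pred * wmap))
    den = float(np.sum((truth + pred) * wmap))
    dice = 1.0 - (num + eps) / (den + eps)
    # quotient rule on (num+eps)/(den+eps)
    dice_grad = -(2.0 * truth * wmap * (den + eps) - (num + eps) * wmap) / (den + eps) ** 2

    terms, included, grads = _lovasz_class_terms(pred, truth, config.absent_class_policy)
    lov_grad = np.zeros_like(pred)
    if included.any():
        w_sum = float(np.sum(w[included]))
        lov = float(np.sum(w[included] * terms[included]) / w_sum)
        for c in range(pred.shape[0]):
            if not included[c]:
                continue
            fg = truth[c].ravel()
            derr_dp = np.sign(pred[c].ravel() - fg)  # d|fg - p|/dp
            lov_grad[c] = (w[c] / w_sum * grads[c] * derr_dp).reshape(pred.shape[1:])
    else:
        lov = 0.0

    value = LossValue(config.alpha * dice + config.beta * lov, dice, lov)
    return value, config.alpha * dice_grad + config.beta * lov_grad
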