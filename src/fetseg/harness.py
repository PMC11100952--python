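"""Training loop around a pluggable prompted-segmenter interface.

The optimisation recipe is the one used for the full prompted fetal-head
model: AdamW (decoupled weight decay) with learning rate and weight decay
both 1e-4, a multi-step schedule dropping the rate by a factor 0.7 at
epochs 10/20/30, the combined weighted Dice + Lovász objective, and early
stopping on validation loss with a patience of 5 epochs.

A segmenter is anything with ``predict(image, boxes) -> C x H x W``
probability map, where ``boxes`` are the per-class prompt rectangles. Two
families are provided:

* :class:`LinearSoftmaxSegmenter` — the trainable surrogate: a per-pixel
  softmax linear model over a small feature stack (intensity terms,
  box-rendered indicator channels, normalised coordinates). It is tiny
  enough to train on a CPU in seconds yet rich enough to exploit the
  prompt boxes, so the loss/optimizer/scheduler/early-stopping machinery
  is exercised end to end. Fine-tuning an actual foundation-model mask
  decoder would slot in behind the same interface.
* Fixed oracle segmenters (:class:`BoxFillSegmenter`,
  :class:`ConstantSegmenter`) for ablation and control experiments.

``ablate_prompts`` sweeps the prompt-box offset (0/10/20 by convention)
re-deriving boxes per offset; ``ablate_losses`` retrains one surrogate per
loss variant (Dice-only, Lovász-only, combined) under a shared seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .class_weights import ClassWeights
from .data_model import DEFAULT_SCHEMA, ImageSample, LabelSchema, decode_argmax, encode_one_hot
from .losses import LossConfig, combined_loss, combined_loss_grad
from .metrics import EvalReport, aggregate_mean, evaluate
from .prompt_boxes import BoundingBox, PromptConfig, boxes_from_label_map

__all__ = [
    "SegmenterInterface",
    "TrainConfig",
    "TrainResult",
    "LinearSoftmaxSegmenter",
    "BoxFillSegmenter",
    "ConstantSegmenter",
    "lr_schedule",
    "train",
    "evaluate_segmenter",
    "ablate_prompts",
    "ablate_losses",
]


@runtime_checkable
class SegmenterInterface(Protocol):
    """Behavioural contract: per-class probabilities from image + prompts."""

    def predict(self, image: np.ndarray, boxes: dict[int, BoundingBox]) -> np.ndarray: ...


@dataclass
class TrainConfig:
    loss: LossConfig
    learning_rate: float = 1e-4
    weight_decay: float = 1e-4
    lr_milestones: tuple[int, ...] = (10, 20, 30)
    lr_gamma: float = 0.7
    early_stop_patience: int = 5
    min_delta: float = 0.0
    max_epochs: int = 40
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("learning_rate must be > 0, weight_decay >= 0")
        if list(self.lr_milestones) != sorted(set(self.lr_milestones)):
            raise ValueError("lr_milestones must be strictly increasing")
        if self.early_stop_patience < 1 or self.max_epochs < 1 or self.batch_size < 1:
            raise ValueError("patience, max_epochs and batch_size must be >= 1")


def lr_schedule(epoch: int, config: TrainConfig) -> float:
    """Multi-step rate: base * gamma^(number of milestones <= epoch)."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    drops = sum(1 for m in config.lr_milestones if m <= epoch)
    return config.learning_rate * config.lr_gamma**drops


def _render_box_channels(
    boxes: dict[int, BoundingBox], shape: tuple[int, int], n_classes: int
) -> np.ndarray:
    out = np.zeros((n_classes, *shape), dtype=np.float64)
    for c in range(n_classes):
        b = boxes.get(c)
        if b is None or b.is_sentinel:
            continue
        out[c, b.y_min : b.y_max + 1, b.x_min : b.x_max + 1] = 1.0
    return out


class LinearSoftmaxSegmenter:
    """Per-pixel softmax linear model over image + prompt-box features.

    Features (scaled by a fixed gain so that 1e-4-sized AdamW steps move
    the logits appreciably): bias, intensity, intensity^2, one indicator
    channel per class box, normalised y and x coordinates.
    """

    FEATURE_GAIN = 100.0

    def __init__(self, n_classes: int = 4, seed: int = 0):
        self.n_classes = n_classes
        self.n_features = 3 + n_classes + 2
        rng = np.random.default_rng(seed & 0x7FFFFFFF)
        self.weights = rng.normal(0.0, 1e-3, (n_classes, self.n_features))

    # -- parameter plumbing -------------------------------------------------
    def get_state(self) -> np.ndarray:
        return self.weights.copy()

    def set_state(self, state: np.ndarray) -> None:
        self.weights = np.asarray(state, dtype=np.float64).copy()

    # -- forward ------------------------------------------------------------
    def _features(self, image: np.ndarray, boxes: dict[int, BoundingBox]) -> np.ndarray:
        h, w = image.shape
        yy, xx = np.indices((h, w), dtype=np.float64)
        chans = [np.ones((h, w)), image, image**2]
        chans.extend(_render_box_channels(boxes, (h, w), self.n_classes))
        chans.extend([yy / max(h - 1, 1), xx / max(w - 1, 1)])
        return np.stack(chans) * self.FEATURE_GAIN

    def _logits(self, feats: np.ndarray) -> np.ndarray:
        return np.einsum("cf,fhw->chw", self.weights, feats, optimize=True)

    @staticmethod
    def _softmax(z: np.ndarray) -> np.ndarray:
        z = z - z.max(axis=0, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=0, keepdims=True)

    def predict(self, image: np.ndarray, boxes: dict[int, BoundingBox]) -> np.ndarray:
        return self._softmax(self._logits(self._features(image, boxes)))

    def loss_and_grad(
        self,
        image: np.ndarray,
        boxes: dict[int, BoundingBox],
        truth_one_hot: np.ndarray,
        loss_cfg: LossConfig,
    ):
        """Combined loss and its gradient w.r.t. the weight matrix."""
        feats = self._features(image, boxes)
        prob = self._softmax(self._logits(feats))
        value, dl_dp = combined_loss_grad(prob, truth_one_hot, loss_cfg)
        # softmax backward: dL/dz_c = p_c * (g_c - sum_k g_k p_k)
        inner = np.sum(dl_dp * prob, axis=0, keepdims=True)
        dl_dz = prob * (dl_dp - inner)
        grad = np.einsum("chw,fhw->cf", dl_dz, feats, optimize=True)
        return value, grad


class BoxFillSegmenter:
    """Oracle that paints every foreground class across its whole prompt
    box (smaller boxes override larger ones), background elsewhere. Its
    accuracy is exactly the tightness of the prompts, so it exposes the
    degradation caused by loosening the box offset."""

    def __init__(self, n_classes: int = 4):
        self.n_classes = n_classes

    def predict(self, image: np.ndarray, boxes: dict[int, BoundingBox]) -> np.ndarray:
        label = np.zeros(image.shape, dtype=np.int64)
        order = sorted(
            (c for c in range(1, self.n_classes) if not boxes[c].is_sentinel),
            key=lambda c: (boxes[c].x_max - boxes[c].x_min + 1)
            * (boxes[c].y_max - boxes[c].y_min + 1),
            reverse=True,
        )
        for c in order:
            b = boxes[c]
            label[b.y_min : b.y_max + 1, b.x_min : b.x_max + 1] = c
        return encode_one_hot(label, LabelSchema(tuple(f"c{i}" for i in range(self.n_classes)))).astype(
            np.float64
        )

    def get_state(self):
        return None


class ConstantSegmenter:
    """Predicts a fixed class everywhere; its loss never improves, so it
    drives the early-stopping path deterministically."""

    def __init__(self, n_classes: int = 4, class_index: int = 0):
        self.n_classes = n_classes
        self.class_index = class_index

    def predict(self, image, boxes):
        prob = np.zeros((self.n_classes, *image.shape))
        prob[self.class_index] = 1.0
        return prob

    def loss_and_grad(self, image, boxes, truth_one_hot, loss_cfg):
        value = combined_loss(self.predict(image, boxes), truth_one_hot, loss_cfg)
        return value, np.zeros(0)

    def get_state(self):
        return None

    def set_state(self, state):
        pass


@dataclass
class TrainResult:
    log: list[dict]
    best_state: object
    best_epoch: int
    best_val_loss: float


def _prepared(samples: Sequence[ImageSample], n_classes: int):
    """Pair each sample with its one-hot truth and offset-0 prompt boxes."""
    schema = LabelSchema(tuple(f"c{i}" for i in range(n_classes)))
    out = []
    for s in samples:
        one_hot = encode_one_hot(s.label_map, schema).astype(np.float64)
        boxes = boxes_from_label_map(s.label_map, PromptConfig(offset=0), schema)
        out.append((s, one_hot, boxes))
    return out


def _dataset_loss(model, prepared, loss_cfg: LossConfig) -> float:
    total = 0.0
    for s, one_hot, boxes in prepared:
        prob = model.predict(s.image, boxes)
        total += combined_loss(prob, one_hot, loss_cfg).total
    return total / len(prepared)


def train(
    model,
    train_set: Sequence[ImageSample],
    val_set: Sequence[ImageSample],
    config: TrainConfig,
) -> TrainResult:
    """AdamW + multi-step LR + early stopping on validation combined loss.

    Improvement means a strict decrease of the validation loss by more
    than ``min_delta``; training halts after ``early_stop_patience``
    consecutive epochs without one, and the best-epoch state is returned.
    """
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and validation sets must be non-empty")
    n_classes = len(config.loss.class_weights)
    train_prep = _prepared(train_set, n_classes)
    val_prep = _prepared(val_set, n_classes)
    rng = np.random.default_rng(config.seed & 0x7FFFFFFF)

    state = model.get_state()
    adam_m = np.zeros_like(state) if state is not None else None
    adam_v = np.zeros_like(state) if state is not None else None
    adam_t = 0

    log: list[dict] = []
    best_val = np.inf
    best_state = copy.deepcopy(state)
    best_epoch = -1
    bad_epochs = 0

    for epoch in range(config.max_epochs):
        lr = lr_schedule(epoch, config)
        order = rng.permutation(len(train_prep))
        train_loss_sum = 0.0
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            grad_sum = None
            for idx in batch:
                s, one_hot, boxes = train_prep[idx]
                value, grad = model.loss_and_grad(s.image, boxes, one_hot, config.loss)
                if not np.isfinite(value.total):
                    raise RuntimeError(
                        f"non-finite loss {value.total} at epoch {epoch}, sample {s.identifier}"
                    )
                train_loss_sum += value.total
                grad_sum = grad if grad_sum is None else grad_sum + grad
            if state is None or grad_sum is None or grad_sum.size == 0:
                continue
            grad_mean = grad_sum / len(batch)
            adam_t += 1
            adam_m = 0.9 * adam_m + 0.1 * grad_mean
            adam_v = 0.999 * adam_v + 0.001 * grad_mean**2
            m_hat = adam_m / (1 - 0.9**adam_t)
            v_hat = adam_v / (1 - 0.999**adam_t)
            # decoupled weight decay, as in AdamW
            state = state - lr * (m_hat / (np.sqrt(v_hat) + 1e-8) + config.weight_decay * state)
            model.set_state(state)

        train_loss = train_loss_sum / len(train_prep)
        val_loss = _dataset_loss(model, val_prep, config.loss)
        log.append({"epoch": epoch, "lr": lr, "train_loss": train_loss, "val_loss": val_loss})

        if val_loss < best_val - config.min_delta:
            best_val = val_loss
            best_state = copy.deepcopy(state)
            best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.early_stop_patience:
                break

    if best_state is not None:
        model.set_state(best_state)
    return TrainResult(log, best_state, best_epoch, float(best_val))


def evaluate_segmenter(
    model,
    samples: Sequence[ImageSample],
    prompt_config: PromptConfig = PromptConfig(),
    schema: LabelSchema = DEFAULT_SCHEMA,
) -> EvalReport:
    """Evaluate a segmenter over a sample set: boxes are derived from the
    truth at the given offset, predictions argmax-decoded, and per-class
    metric triples averaged across samples."""
    if len(samples) == 0:
        raise ValueError("empty sample set")
    acc: dict[str, list[tuple[float, float, float]]] = {n: [] for n in schema.class_names}
    for s in samples:
        boxes = boxes_from_label_map(s.label_map, prompt_config, schema)
        pred = decode_argmax(model.predict(s.image, boxes))
        rep = evaluate(pred, s.label_map, schema)
        for name, triple in rep.per_class.items():
            acc[name].append(triple)
    per_class = {
        name: tuple(aggregate_mean(t[i] for t in triples) for i in range(3))
        for name, triples in acc.items()
    }
    return EvalReport(per_class)


def ablate_prompts(
    model,
    dataset: Sequence[ImageSample],
    offsets: Sequence[int] = (0, 10, 20),
    schema: LabelSchema = DEFAULT_SCHEMA,
    threshold: float = 0.5,
) -> dict[int, EvalReport]:
    """Re-evaluate a fixed segmenter with prompt boxes loosened by each
    offset in turn."""
    return {
        off: evaluate_segmenter(model, dataset, PromptConfig(threshold, off), schema)
        for off in offsets
    }


def ablate_losses(
    model_factory,
    train_set: Sequence[ImageSample],
    val_set: Sequence[ImageSample],
    base_config: TrainConfig,
    variants: Sequence[str] = ("dice", "lovasz", "combined"),
    schema: LabelSchema = DEFAULT_SCHEMA,
) -> dict[str, EvalReport]:
    """Train one fresh surrogate per loss variant under a shared seed and
    evaluate each on the same validation set."""
    mixes = {"dice": (1.0, 0.0), "lovasz": (0.0, 1.0), "combined": (0.5, 0.5)}
    out = {}
    for variant in variants:
        alpha, beta = mixes[variant]
        cfg = replace(base_config, loss=replace(base_config.loss, alpha=alpha, beta=beta))
        model = model_factory()
        train(model, train_set, val_set, cfg)
        out[variant] = evaluate_segmenter(model, val_set, PromptConfig(offset=0), schema)
    return out
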