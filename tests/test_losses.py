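import numpy as np
import pytest

from fetseg import (
    ClassWeights,
    LossConfig,
    combined_loss,
    encode_one_hot,
    weighted_dice_loss,
    weighted_lovasz_loss,
)
from fetseg.losses import combined_loss_grad

W2 = ClassWeights((0.5, 0.5))
W4 = ClassWeights((0.1, 0.1, 0.9, 0.7))


def hard_prediction(label_map, n_classes):
    from fetseg import LabelSchema

    schema = LabelSchema(tuple(f"c{i}" for i in range(n_classes)))
    return encode_one_hot(label_map, schema).astype(np.float64)


def jaccard_loss_oracle(pred_labels, truth_labels, c):
    """Set-arithmetic 1 - IoU for one class; empty/empty counts as 0 loss."""
    a = pred_labels == c
    b = truth_labels == c
    union = (a | b).sum()
    if union == 0:
        return 0.0
    return 1.0 - (a & b).sum() / union


def lovasz_extension_oracle(errors, fg):
    """The Lovász extension evaluated from its definition: order the error
    vector descending and accumulate the Jaccard-loss increments of the
    growing mispredicted prefix set."""

    def jaccard_of_prefix(indices):
        mis = np.zeros(len(fg), dtype=bool)
        mis[list(indices)] = True
        # mispredicted set S: predicted-as-set = fg XOR S
        pred_set = fg.astype(bool) ^ mis
        union = (pred_set | fg.astype(bool)).sum()
        if union == 0:
            return 0.0
        return 1.0 - (pred_set & fg.astype(bool)).sum() / union

    perm = np.argsort(-errors, kind="stable")
    total, prev = 0.0, 0.0
    for k in range(len(errors)):
        cur = jaccard_of_prefix(perm[: k + 1])
        total += errors[perm[k]] * (cur - prev)
        prev = cur
    return total


def test_dice_zero_at_perfect_prediction(rng):
    truth = rng.integers(0, 4, (6, 6))
    pred = hard_prediction(truth, 4)
    assert weighted_dice_loss(pred, pred, W4) == pytest.approx(0.0, abs=1e-5)


def test_dice_hand_worked_two_pixel_example():
    truth = hard_prediction(np.array([[0, 1]]), 2)
    pred = hard_prediction(np.array([[0, 0]]), 2)
    assert weighted_dice_loss(pred, truth, W2) == pytest.approx(0.5, abs=1e-5)


def test_dice_tends_to_one_with_zero_overlap():
    truth = hard_prediction(np.array([[0, 0]]), 2)
    pred = hard_prediction(np.array([[1, 1]]), 2)
    assert weighted_dice_loss(pred, truth, W2, epsilon=1e-12) == pytest.approx(1.0, abs=1e-9)


def test_uniform_weights_reduce_to_unweighted_dice(rng):
    truth = hard_prediction(rng.integers(0, 4, (5, 5)), 4)
    pred = rng.dirichlet(np.ones(4), size=(5, 5)).transpose(2, 0, 1)
    uniform = ClassWeights.uniform(4)
    unweighted = 1.0 - (2 * (truth * pred).sum() + 1e-6) / ((truth + pred).sum() + 1e-6)
    assert weighted_dice_loss(pred, truth, uniform) == pytest.approx(unweighted)


def test_dice_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        weighted_dice_loss(np.zeros((2, 2, 2)), np.zeros((2, 3, 2)), W2)


def test_lovasz_zero_at_perfect_prediction(rng):
    truth = rng.integers(0, 4, (6, 6))
    pred = hard_prediction(truth, 4)
    assert weighted_lovasz_loss(pred, pred, W4) == pytest.approx(0.0)


def test_lovasz_hand_worked_vertex_example():
    truth = hard_prediction(np.array([[0, 1]]), 2)
    pred = hard_prediction(np.array([[0, 0]]), 2)
    # class 0: IoU 1/2, class 1: IoU 0 -> weighted mean of (0.5, 1.0) = 0.75
    assert weighted_lovasz_loss(pred, truth, W2) == pytest.approx(0.75)


def test_lovasz_equals_jaccard_at_binary_vertices(rng):
    """At every hard prediction the class terms must equal 1 - IoU from
    explicit set arithmetic (>=200 random cases, absent classes included)."""
    for _ in range(200):
        n_classes = int(rng.integers(2, 5))
        h, w = rng.integers(1, 6, size=2)
        truth_lm = rng.integers(0, n_classes, (h, w))
        pred_lm = rng.integers(0, n_classes, (h, w))
        weights = ClassWeights(tuple(rng.uniform(0.1, 1.0, n_classes)))
        got = weighted_lovasz_loss(
            hard_prediction(pred_lm, n_classes), hard_prediction(truth_lm, n_classes), weights
        )
        wa = weights.as_array()
        expected = sum(
            wa[c] * jaccard_loss_oracle(pred_lm, truth_lm, c) for c in range(n_classes)
        ) / wa.sum()
        assert got == pytest.approx(expected, abs=1e-12)


def test_lovasz_matches_extension_oracle_on_soft_predictions(rng):
    """Soft probabilities on <=6-pixel grids against the definitional
    Lovász extension coded independently."""
    for _ in range(100):
        n_classes = int(rng.integers(2, 4))
        n_pix = int(rng.integers(1, 7))
        truth_lm = rng.integers(0, n_classes, (1, n_pix))
        pred = rng.dirichlet(np.ones(n_classes), size=(1, n_pix)).transpose(2, 0, 1)
        weights = ClassWeights(tuple(rng.uniform(0.1, 1.0, n_classes)))
        truth = hard_prediction(truth_lm, n_classes)
        got = weighted_lovasz_loss(pred, truth, weights)
        wa = weights.as_array()
        terms = []
        for c in range(n_classes):
            fg = truth[c].ravel()
            errors = np.abs(fg - pred[c].ravel())
            terms.append(lovasz_extension_oracle(errors, fg))
        expected = float(np.dot(wa, terms) / wa.sum())
        assert got == pytest.approx(expected, abs=1e-10)


def test_lovasz_bounded_in_unit_interval(rng):
    for _ in range(50):
        pred = rng.dirichlet(np.ones(4), size=(3, 3)).transpose(2, 0, 1)
        truth = hard_prediction(rng.integers(0, 4, (3, 3)), 4)
        val = weighted_lovasz_loss(pred, truth, W4)
        assert 0.0 <= val <= 1.0


def test_absent_class_skip_policy(rng):
    truth_lm = np.zeros((3, 3), dtype=int)
    truth_lm[1:] = 1  # classes 0 and 1 present; 2 and 3 absent
    truth = hard_prediction(truth_lm, 4)
    pred = rng.dirichlet(np.ones(4), size=(3, 3)).transpose(2, 0, 1)
    penalty = weighted_lovasz_loss(pred, truth, W4, absent_class_policy="penalty")
    skip = weighted_lovasz_loss(pred, truth, W4, absent_class_policy="skip")
    wa = W4.as_array()
    # skip = weighted mean over the present classes (0, 1) only
    terms = []
    for c in (0, 1):
        fg = truth[c].ravel()
        errors = np.abs(fg - pred[c].ravel())
        terms.append(lovasz_extension_oracle(errors, fg))
    assert skip == pytest.approx(float(np.dot(wa[:2], terms) / wa[:2].sum()), abs=1e-10)
    # penalty additionally folds in the absent classes' max-error terms
    for c in (2, 3):
        terms.append(np.abs(pred[c]).max())
    assert penalty == pytest.approx(float(np.dot(wa, terms) / wa.sum()), abs=1e-10)


def test_combined_is_linear_blend():
    truth = hard_prediction(np.array([[0, 1]]), 2)
    pred = hard_prediction(np.array([[0, 0]]), 2)
    cfg = LossConfig(W2, alpha=0.5, beta=0.5)
    lv = combined_loss(pred, truth, cfg)
    assert lv.dice_term == pytest.approx(0.5, abs=1e-5)
    assert lv.lovasz_term == pytest.approx(0.75)
    assert lv.total == pytest.approx(0.625, abs=1e-5)
    assert lv.total == pytest.approx(0.5 * lv.dice_term + 0.5 * lv.lovasz_term)
    only_dice = combined_loss(pred, truth, LossConfig(W2, alpha=1.0, beta=0.0))
    assert only_dice.total == only_dice.dice_term


def test_default_config_mix_is_half_half():
    cfg = LossConfig(W4)
    assert cfg.alpha == 0.5 and cfg.beta == 0.5


def test_analytic_gradient_matches_finite_differences(rng):
    """The harness's analytic gradient against central differences on the
    smooth (Dice) and piecewise-linear (Lovász) components."""
    cfg = LossConfig(ClassWeights((0.3, 0.7)), alpha=0.5, beta=0.5)
    truth = hard_prediction(rng.integers(0, 2, (2, 3)), 2)
    pred = rng.uniform(0.05, 0.95, (2, 2, 3))
    _, grad = combined_loss_grad(pred, truth, cfg)
    eps = 1e-7
    for c in range(2):
        for y in range(2):
            for x in range(3):
                up, dn = pred.copy(), pred.copy()
                up[c, y, x] += eps
                dn[c, y, x] -= eps
                fd = (
                    combined_loss(up, truth, cfg).total - combined_loss(dn, truth, cfg).total
                ) / (2 * eps)
                assert grad[c, y, x] == pytest.approx(fd, abs=1e-5)
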