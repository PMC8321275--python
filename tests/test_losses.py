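"""The loss family: hard/soft forms, gradients, weighting rules."""

import numpy as np
import pytest

from segloss import (
    ClassSet,
    LabelMap,
    LossSpec,
    PRESETS,
    class_balance_weights,
    dice_loss,
    evaluate_loss,
    iou_loss,
    iouxy_loss,
    make_nobk,
    one_hot,
    weighted_cross_entropy,
)

from conftest import random_labelmap


def finite_difference_grad(s, gnd, spec, h=1e-6):
    num = np.zeros_like(s)
    for idx in np.ndindex(s.shape):
        sp, sm = s.copy(), s.copy()
        sp[idx] += h
        sm[idx] -= h
        num[idx] = (
            evaluate_loss(sp, gnd, spec).value - evaluate_loss(sm, gnd, spec).value
        ) / (2 * h)
    return num


class TestLossSpec:
    def test_alpha_beta_constraint(self):
        with pytest.raises(ValueError, match="alpha \\+ beta"):
            LossSpec("iou", alpha=1.5, beta=1.0)
        with pytest.raises(ValueError, match="nonnegative"):
            LossSpec("iou", alpha=2.5, beta=-0.5)
        LossSpec("iou", alpha=2.0, beta=0.0)  # boundary is legal

    def test_unknown_family(self):
        with pytest.raises(ValueError, match="unknown loss family"):
            LossSpec("tversky")

    def test_negative_class_weight(self):
        with pytest.raises(ValueError, match="nonnegative"):
            LossSpec("crossE", class_weights=(1.0, -1.0))


class TestCrossEntropy:
    def test_perfect_prediction_is_zero_up_to_clamp(self, rng, cs3):
        gnd = random_labelmap(rng, cs3, (5, 5))
        v = weighted_cross_entropy(one_hot(gnd), gnd)
        assert v.value == pytest.approx(0.0, abs=1e-9)

    def test_half_score_single_pixel(self):
        """One pixel with true-class score 0.5 costs -ln(0.5)."""
        cs = ClassSet((0, 1))
        gnd = LabelMap(np.array([[1]]), cs)
        prob = np.array([[[0.5, 0.5]]])
        v = weighted_cross_entropy(prob, gnd)
        assert v.value == pytest.approx(-np.log(0.5), abs=1e-9)

    def test_linearity_in_class_weights(self, rng, cs3):
        gnd = random_labelmap(rng, cs3, (4, 4))
        prob = rng.dirichlet(np.ones(3), size=(4, 4))
        w1 = LossSpec("crossE", class_weights=(1.0, 1.0, 1.0))
        w2 = LossSpec("crossE", class_weights=(2.0, 2.0, 2.0))
        v1 = weighted_cross_entropy(prob, gnd, w1).value
        v2 = weighted_cross_entropy(prob, gnd, w2).value
        assert v2 == pytest.approx(2 * v1)

    def test_cross_entropy_exceeds_one_for_poor_predictions(self):
        # crossE is unbounded above, unlike the count-family losses
        cs = ClassSet((0, 1))
        gnd = LabelMap(np.array([[1]]), cs)
        prob = np.array([[[0.99, 0.01]]])
        assert weighted_cross_entropy(prob, gnd).value > 1.0


class TestCountLosses:
    def test_perfect_hard_prediction_is_zero(self, rng, cs3):
        lm = random_labelmap(rng, cs3, (6, 6))
        assert iou_loss(lm, lm).value == 0.0
        assert dice_loss(lm, lm).value == 0.0

    def test_hard_value_against_confusion_oracle(self, rng, cs3):
        from segloss import per_class_confusion

        gnd = random_labelmap(rng, cs3, (8, 8))
        seg = random_labelmap(rng, cs3, (8, 8))
        counts = per_class_confusion(gnd, seg)
        eps = PRESETS["iou"].smoothing_eps
        expect = 1.0 - np.mean(
            [(counts.tp[i] + eps) / (counts.tp[i] + counts.fp[i] + counts.fn[i] + eps)
             for i in range(3)]
        )
        assert iou_loss(seg, gnd).value == pytest.approx(expect, abs=1e-12)

    def test_dice_single_class_example(self):
        """TP=1, FP=1, FN=2 for the single included class: loss 1 - 2/5."""
        cs = ClassSet((0, 1))
        gnd = LabelMap(np.array([[1, 1, 1, 0, 0]]), cs)
        seg = LabelMap(np.array([[1, 0, 0, 1, 0]]), cs)
        v = dice_loss(seg, gnd, make_nobk(PRESETS["dice"]))
        assert v.value == pytest.approx(0.6, abs=1e-6)

    def test_iouxy_single_class_example(self):
        """TP=2, FP=2, FN=0, alpha=0.5: per-class term 2/3, loss 1/3."""
        cs = ClassSet((0, 1))
        gnd = LabelMap(np.array([[1, 1, 0, 0]]), cs)
        seg = LabelMap(np.array([[1, 1, 1, 1]]), cs)
        spec = make_nobk(LossSpec("iou", alpha=0.5, beta=1.5))
        assert iouxy_loss(seg, gnd, spec).value == pytest.approx(1 / 3, abs=1e-6)

    def test_dice_le_iou_everywhere(self, rng, cs3):
        for _ in range(100):
            gnd = random_labelmap(rng, cs3, (6, 6))
            seg = random_labelmap(rng, cs3, (6, 6))
            assert dice_loss(seg, gnd).value <= iou_loss(seg, gnd).value + 1e-12

    def test_iouxy_reduces_to_iou_bit_identically(self, rng, cs3):
        gnd = random_labelmap(rng, cs3, (7, 7))
        seg = random_labelmap(rng, cs3, (7, 7))
        spec11 = LossSpec("iou", alpha=1.0, beta=1.0)
        assert iouxy_loss(seg, gnd, spec11).value == iou_loss(seg, gnd).value

    def test_iouxy_monotone_in_alpha_when_fn_zero(self):
        cs = ClassSet((0, 1))
        gnd = LabelMap(np.array([[1, 1, 0, 0]]), cs)
        seg = LabelMap(np.array([[1, 1, 1, 0]]), cs)  # FP=1, FN=0 for class 1
        losses = [
            iouxy_loss(seg, gnd, make_nobk(LossSpec("iou", alpha=a, beta=2 - a))).value
            for a in (0.0, 0.5, 1.0, 1.5, 2.0)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(losses, losses[1:]))

    def test_soft_on_onehot_equals_hard(self, rng, cs3):
        for _ in range(20):
            gnd = random_labelmap(rng, cs3, (8, 8))
            seg = random_labelmap(rng, cs3, (8, 8))
            for name in ("iou", "dice", "iou0515", "dice_noBK"):
                spec = PRESETS[name]
                hard = evaluate_loss(seg, gnd, spec).value
                soft = evaluate_loss(one_hot(seg), gnd, spec).value
                assert soft == pytest.approx(hard, abs=1e-6)

    def test_range_and_zero_iff_perfect(self, rng, cs3):
        gnd = random_labelmap(rng, cs3, (6, 6))
        seg = random_labelmap(rng, cs3, (6, 6))
        for name in ("iou", "dice", "iou0515"):
            v = evaluate_loss(seg, gnd, PRESETS[name]).value
            assert 0.0 <= v <= 1.0
            if not np.array_equal(seg.values, gnd.values):
                assert v > 0.0


class TestGradients:
    @pytest.mark.parametrize("name", ["crossE", "iou", "dice", "iou0515", "dice_noBK"])
    def test_finite_difference(self, name, rng, cs3):
        gnd = random_labelmap(rng, cs3, (4, 4))
        s = rng.uniform(0.05, 0.95, size=(4, 4, 3))
        spec = PRESETS[name]
        _, grad = evaluate_loss(s, gnd, spec, return_grad=True)
        num = finite_difference_grad(s, gnd, spec)
        assert np.abs(grad - num).max() < 1e-4


class TestNoBK:
    def test_nobk_ignores_extra_background(self):
        """Appending correctly-background pixels leaves dice noBK unchanged."""
        cs = ClassSet((0, 1))
        gnd = LabelMap(np.array([[1, 1, 0, 0]]), cs)
        seg = LabelMap(np.array([[1, 0, 1, 0]]), cs)
        spec = make_nobk(PRESETS["dice"])
        base = dice_loss(seg, gnd, spec).value
        gnd2 = LabelMap(np.hstack([gnd.values, np.zeros((1, 8), int)]), cs)
        seg2 = LabelMap(np.hstack([seg.values, np.zeros((1, 8), int)]), cs)
        assert dice_loss(seg2, gnd2, spec).value == pytest.approx(base, abs=1e-9)

    def test_nobk_single_class_equals_uniclass(self, rng):
        cs = ClassSet((0, 1))
        gnd = random_labelmap(rng, cs, (6, 6))
        seg = random_labelmap(rng, cs, (6, 6))
        nobk = dice_loss(seg, gnd, make_nobk(PRESETS["dice"])).value
        from segloss import per_class_confusion

        c = per_class_confusion(gnd, seg).for_class(1)
        eps = PRESETS["dice"].smoothing_eps
        uniclass = 1 - (2 * c["tp"] + eps) / (2 * c["tp"] + c["fp"] + c["fn"] + eps)
        assert nobk == pytest.approx(uniclass, abs=1e-9)

    def test_make_nobk_rejects_crossE(self):
        with pytest.raises(ValueError, match="background class weight"):
            make_nobk(PRESETS["crossE"])


class TestClassBalance:
    def test_inverse_frequency_example(self):
        """Frequencies (0.95, 0.05) give mean-1 weights (0.1, 1.9)."""
        cs = ClassSet((0, 1))
        values = np.zeros((10, 10), dtype=int)
        values[0, :5] = 1
        w = class_balance_weights(LabelMap(values, cs))
        assert w == pytest.approx([2 / 19 * 0.95, 2 * 0.95], rel=1e-12)
        assert w.mean() == pytest.approx(1.0)
        assert w[1] == pytest.approx(1.9)

    def test_uniform_frequencies_give_unit_weights(self):
        cs = ClassSet((0, 1))
        values = np.array([[0, 1], [1, 0]])
        w = class_balance_weights(LabelMap(values, cs))
        np.testing.assert_allclose(w, 1.0)

    def test_invariant_to_dataset_duplication(self, rng, cs3):
        lm = random_labelmap(rng, cs3, (8, 8))
        w1 = class_balance_weights([lm])
        w2 = class_balance_weights([lm, lm, lm])
        np.testing.assert_allclose(w1, w2)

    def test_missing_class_is_flagged(self, cs3):
        lm = LabelMap(np.array([[0, 1], [1, 0]]), cs3)  # class 2 absent
        with pytest.warns(UserWarning, match="no pixels"):
            w = class_balance_weights(lm)
        assert np.isfinite(w).all()
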