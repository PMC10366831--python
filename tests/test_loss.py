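"""Tversky index, focal Tversky loss, combined dual-task loss."""

import numpy as np
import pytest

from vctdbt.loss import (LossConfig, combined_loss, combined_loss_grad,
                         focal_tversky_loss, one_hot, to_outline_targets,
                         tversky_index)


def brute_force_tversky(p, g, c, alpha, beta, eps):
    """Independent oracle: explicit per-voxel summation loops."""
    tp = fn = fp = 0.0
    pc, gc = p[c], g[c]
    for idx in np.ndindex(pc.shape):
        tp += pc[idx] * gc[idx]
        fn += (1 - pc[idx]) * gc[idx]
        fp += pc[idx] * (1 - gc[idx])
    return (tp + eps) / (tp + alpha * fn + beta * fp + eps)


def random_maps(rng, shape=(4, 4, 4)):
    logits = rng.normal(size=(3,) + shape)
    e = np.exp(logits - logits.max(axis=0))
    p = e / e.sum(axis=0)
    g = one_hot(rng.integers(0, 3, shape).astype(np.uint8))
    return p, g


class TestTverskyIndex:
    def test_matches_brute_force_oracle(self, rng):
        cfg = LossConfig()
        for _ in range(25):
            p, g = random_maps(rng)
            for c in range(3):
                ti = tversky_index(p, g, c, cfg)
                oracle = brute_force_tversky(p, g, c, cfg.alpha, cfg.beta,
                                             cfg.epsilon)
                assert ti == pytest.approx(oracle, abs=1e-9)

    def test_perfect_prediction_is_one(self):
        g = one_hot(np.array([[[0, 1], [2, 1]]], np.uint8))
        assert tversky_index(g.copy(), g, 1, LossConfig()) == pytest.approx(1.0)

    def test_hand_computed_two_voxel_case(self):
        """p_c=(1,0), g_c=(1,1): TI = 1/(1+alpha) with alpha=0.7."""
        p = np.zeros((3, 2, 1, 1))
        g = np.zeros((3, 2, 1, 1))
        p[1, 0] = 1.0
        p[0, 1] = 1.0
        g[1, :] = 1.0
        cfg = LossConfig(epsilon=1e-12)
        assert tversky_index(p, g, 1, cfg) == pytest.approx(1 / 1.7, abs=1e-6)

    def test_equal_weights_reduce_to_soft_dice(self, rng):
        cfg = LossConfig(alpha=0.5, beta=0.5, epsilon=1e-12)
        for _ in range(10):
            p, g = random_maps(rng)
            for c in range(3):
                tp = (p[c] * g[c]).sum()
                fn = ((1 - p[c]) * g[c]).sum()
                fp = (p[c] * (1 - g[c])).sum()
                dice = 2 * tp / (2 * tp + fn + fp)
                assert tversky_index(p, g, c, cfg) == pytest.approx(dice, abs=1e-9)

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(20):
            p, g = random_maps(rng)
            for c in range(3):
                assert 0.0 <= tversky_index(p, g, c) <= 1.0

    def test_shape_mismatch_rejected(self, rng):
        p, g = random_maps(rng)
        with pytest.raises(ValueError):
            tversky_index(p, g[:, :2], 0)

    def test_invalid_probabilities_rejected(self, rng):
        p, g = random_maps(rng)
        with pytest.raises(ValueError):
            tversky_index(p * 3, g, 0)


class TestFocalTverskyLoss:
    def test_perfect_prediction_zero(self):
        g = one_hot(np.array([[[0, 1, 2]]], np.uint8))
        assert focal_tversky_loss(g.copy(), g) == pytest.approx(0.0, abs=1e-4)

    def test_half_ti_to_the_gamma(self):
        """(1 - 0.5)^0.75 ~ 0.5946 for a single class with TI = 0.5."""
        assert 0.5 ** 0.75 == pytest.approx(0.59460, abs=1e-4)
        # realize TI=0.5 with alpha=beta=0.5: p=(1,0), g=(1,1) gives dice 2/3,
        # so build TI=0.5 directly: TP=1, FN=2 -> 1/(1+0.5*2)=0.5
        p = np.zeros((3, 3, 1, 1))
        g = np.zeros((3, 3, 1, 1))
        p[0, 0] = 1.0
        g[0, :] = 1.0
        cfg = LossConfig(alpha=0.5, beta=0.5, gamma=0.75, epsilon=1e-12)
        assert focal_tversky_loss(p, g, classes=(0,), cfg=cfg) == pytest.approx(
            0.5 ** 0.75, abs=1e-6)

    def test_gamma_one_is_plain_sum(self, rng):
        cfg1 = LossConfig(gamma=1.0)
        for _ in range(5):
            p, g = random_maps(rng)
            expected = sum(1 - tversky_index(p, g, c, cfg1) for c in range(3))
            assert focal_tversky_loss(p, g, cfg=cfg1) == pytest.approx(
                expected, abs=1e-12)

    def test_empty_class_set_rejected(self, rng):
        p, g = random_maps(rng)
        with pytest.raises(ValueError):
            focal_tversky_loss(p, g, classes=())

    def test_interpolating_toward_truth_decreases_loss(self, rng):
        for _ in range(10):
            p, g = random_maps(rng)
            losses = [focal_tversky_loss((1 - t) * p + t * g, g)
                      for t in (0.0, 0.3, 0.7, 1.0)]
            assert np.all(np.diff(losses) < 0)


class TestOutlineTargets:
    def test_air_channel_unchanged(self, rng):
        p, g = random_maps(rng)
        assert np.array_equal(to_outline_targets(g)[0], g[0])

    def test_tissue_probabilities_sum(self):
        p = np.zeros((3, 1, 1, 1))
        p[1] = 0.3
        p[2] = 0.5
        assert to_outline_targets(p)[1][0, 0, 0] == pytest.approx(0.8)

    def test_all_air_volume_empty_tissue(self):
        g = one_hot(np.zeros((2, 2, 2), np.uint8))
        assert np.all(to_outline_targets(g)[1] == 0)


class TestCombinedLoss:
    def test_zero_weight_equals_loss1(self, rng):
        cfg = LossConfig(lambda_outline=0.0)
        for _ in range(5):
            p, g = random_maps(rng)
            assert combined_loss(p, g, cfg) == pytest.approx(
                focal_tversky_loss(p, g, cfg.loss1_classes, cfg), abs=1e-12)

    def test_additivity(self, rng):
        cfg = LossConfig(lambda_outline=0.7)
        for _ in range(5):
            p, g = random_maps(rng)
            loss1 = focal_tversky_loss(p, g, cfg.loss1_classes, cfg)
            loss2 = focal_tversky_loss(to_outline_targets(p),
                                       to_outline_targets(g), (0, 1), cfg)
            assert combined_loss(p, g, cfg) == pytest.approx(
                loss1 + 0.7 * loss2, abs=1e-12)

    def test_perfect_prediction_zero_any_lambda(self):
        g = one_hot(np.array([[[0, 1], [2, 0]]], np.uint8))
        for lam in (0.0, 1.0, 3.0):
            assert combined_loss(g.copy(), g, LossConfig(lambda_outline=lam)) \
                == pytest.approx(0.0, abs=1e-3)


class TestCombinedLossGrad:
    def test_value_matches_forward(self, rng):
        cfg = LossConfig()
        p, g = random_maps(rng)
        value, _ = combined_loss_grad(p, g, cfg)
        assert value == pytest.approx(combined_loss(p, g, cfg), abs=1e-12)

    def test_gradient_matches_finite_differences(self, rng):
        cfg = LossConfig()
        p, g = random_maps(rng, shape=(3, 2, 2))
        _, grad = combined_loss_grad(p, g, cfg)
        eps = 1e-6
        for _ in range(20):
            c = rng.integers(3)
            idx = tuple(rng.integers(s) for s in p.shape[1:])
            pp = p.copy()
            pp[(c,) + idx] += eps
            pm = p.copy()
            pm[(c,) + idx] -= eps
            num = (combined_loss(pp, g, cfg) - combined_loss(pm, g, cfg)) / (2 * eps)
            assert grad[(c,) + idx] == pytest.approx(num, abs=1e-5)
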