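"""Compound losses vs a brute-force per-voxel oracle; burden metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petseg.losses_metrics import (dice_score, loss_2d, loss_3d,
                                   soft_dice_term, tumor_metrics,
                                   voxel_sensitivity, weighted_bce_term)

# ---------------------------------------------------------------------------
# Independent oracle: literal per-voxel loops, no shared code with petseg
# ---------------------------------------------------------------------------

def oracle_loss_2d(pred, target):
    p = pred.ravel()
    y = target.ravel()
    sp = st_ = inter = 0.0
    for i in range(p.size):
        sp += p[i]
        st_ += y[i]
        inter += p[i] * y[i]
    dice = 1.0 - (2.0 * inter + 1e-6) / (sp + st_ + 1e-6)
    w = p.size / max(st_, 1.0)
    ce = 0.0
    for i in range(p.size):
        pi = min(max(p[i], 1e-7), 1 - 1e-7)
        ce += -(w * y[i] * math.log(pi) + (1 - y[i]) * math.log(1 - pi))
    return dice + ce / p.size


def oracle_loss_3d(pred, target):
    p = pred.ravel()
    y = target.ravel()
    sp = st_ = inter = mae = 0.0
    for i in range(p.size):
        sp += p[i]
        st_ += y[i]
        inter += p[i] * y[i]
        mae += abs(y[i] - p[i])
    dice = 1.0 - (2.0 * inter + 1e-6) / (sp + st_ + 1e-6)
    sens = 1.0 - (inter + 1e-6) / (st_ + 1e-6)
    return dice + sens + mae / p.size


class TestOracleEquivalence:
    def test_loss_2d_matches_bruteforce_on_random_tensors(self):
        """Dice + weighted BCE equals the voxel-loop oracle to 1e-6."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            shape = tuple(rng.integers(2, 9, size=2))
            pred = rng.random(shape)
            target = (rng.random(shape) > 0.6).astype(float)
            rep = loss_2d(pred, target)
            assert rep.total == pytest.approx(oracle_loss_2d(pred, target),
                                              abs=1e-6)
            assert rep.total == pytest.approx(
                rep["dice_term"] + rep["ce_term"], abs=1e-9)

    def test_loss_3d_matches_bruteforce_on_random_tensors(self):
        """Dice + sensitivity + MAE equals the voxel-loop oracle to 1e-6."""
        rng = np.random.default_rng(6)
        for _ in range(100):
            shape = tuple(rng.integers(2, 6, size=3))
            pred = rng.random(shape)
            target = (rng.random(shape) > 0.5).astype(float)
            rep = loss_3d(pred, target)
            assert rep.total == pytest.approx(oracle_loss_3d(pred, target),
                                              abs=1e-6)
            assert rep.total == pytest.approx(
                rep["dice_term"] + rep["sensitivity_term"] + rep["mae_term"],
                abs=1e-9)


class TestAnalyticAnchors:
    def test_perfect_prediction_zeroes_3d_loss(self):
        y = np.zeros((4, 4, 4))
        y[1:3, 1:3, 1:3] = 1
        assert loss_3d(y, y).total == pytest.approx(0.0, abs=1e-5)

    def test_hard_complement_reaches_maximum_three(self):
        y = np.zeros((4, 4, 4))
        y[1:3, 1:3, 1:3] = 1
        rep = loss_3d(1.0 - y, y)
        assert rep.total == pytest.approx(3.0, abs=1e-4)
        for term in rep.terms.values():
            assert 0.0 <= term <= 1.0 + 1e-9

    def test_disjoint_hard_prediction_dice_term_is_one(self):
        y = np.zeros((4, 4)); y[:2] = 1
        p = np.zeros((4, 4)); p[2:] = 1
        assert float(soft_dice_term(p, y).data) == pytest.approx(1.0, abs=1e-4)

    def test_dice_half_overlap_hand_value(self):
        """|P|=4, |T|=4, |P∩T|=2 -> Dice bracket 0.5."""
        p = np.zeros(8); p[:4] = 1
        y = np.zeros(8); y[2:6] = 1
        assert float(soft_dice_term(p, y).data) == pytest.approx(0.5, abs=1e-6)

    def test_weighted_bce_two_voxel_hand_value(self):
        """y=(1,0), p=(.5,.5), w=2 -> 1.5*log2."""
        val = float(weighted_bce_term(np.array([0.5, 0.5]),
                                      np.array([1.0, 0.0])).data)
        assert val == pytest.approx(1.5 * math.log(2), abs=1e-9)

    def test_weighted_bce_all_negative_target(self):
        """No positives: weight term vanishes, mean -log(1-p) remains."""
        val = float(weighted_bce_term(np.full(10, 0.5), np.zeros(10)).data)
        assert val == pytest.approx(math.log(2), abs=1e-9)

    def test_perfect_2d_prediction_near_zero(self):
        y = (np.random.default_rng(0).random((6, 6)) > 0.5).astype(float)
        assert loss_2d(y, y).total < 1e-5


class TestLossProperties:
    def test_3d_total_bounded_by_three(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = rng.random((4, 4, 4))
            y = (rng.random((4, 4, 4)) > 0.5).astype(float)
            rep = loss_3d(p, y)
            assert 0.0 <= rep.total <= 3.0 + 1e-9

    def test_moving_probability_toward_target_never_increases_3d_loss(self):
        rng = np.random.default_rng(8)
        p = rng.random((3, 3, 3))
        y = (rng.random((3, 3, 3)) > 0.5).astype(float)
        base = loss_3d(p, y).total
        for idx in np.ndindex(p.shape):
            p2 = p.copy()
            p2[idx] = p2[idx] + 0.5 * (y[idx] - p2[idx])  # halfway to target
            assert loss_3d(p2, y).total <= base + 1e-12

    def test_empty_target_sensitivity_term_is_zero(self):
        rep = loss_3d(np.full((3, 3, 3), 0.2), np.zeros((3, 3, 3)))
        assert rep["sensitivity_term"] == pytest.approx(0.0, abs=1e-6)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            loss_2d(np.zeros((2, 2)), np.zeros((3, 3)))
        with pytest.raises(ValueError):
            loss_3d(np.zeros((2, 2, 2)), np.zeros((2, 2, 3)))

    def test_literal_printed_bce_variant_differs(self):
        """The as-published algebraic form is exposed but not equivalent."""
        p = np.array([0.5, 0.5]); y = np.array([1.0, 0.0])
        lit = float(weighted_bce_term(p, y, literal=True).data)
        std = float(weighted_bce_term(p, y).data)
        assert lit != pytest.approx(std, abs=1e-3)

    def test_loss_is_differentiable_for_training(self):
        from petseg.nn import Tensor
        p = Tensor(np.full((2, 2), 0.4), requires_grad=True)
        rep = loss_3d(p, np.eye(2))
        rep.total_tensor.backward()
        assert p.grad is not None and np.isfinite(p.grad).all()


class TestMaskMetrics:
    def test_dice_identity_and_symmetry(self):
        rng = np.random.default_rng(9)
        a = rng.random((5, 5, 5)) > 0.5
        b = rng.random((5, 5, 5)) > 0.5
        assert dice_score(a, a) == 1.0
        assert dice_score(a, b) == dice_score(b, a)
        assert dice_score(np.zeros((2, 2, 2)), np.zeros((2, 2, 2))) == 1.0

    def test_sensitivity_counts_and_empty_flag(self):
        t = np.zeros((2, 2, 2)); t.ravel()[:4] = 1
        p = np.zeros((2, 2, 2)); p.ravel()[:3] = 1
        val, flag = voxel_sensitivity(p, t)
        assert val == pytest.approx(0.75) and not flag
        val, flag = voxel_sensitivity(p, np.zeros((2, 2, 2)))
        assert val == 1.0 and flag


class TestTumorMetrics:
    def test_hundred_voxels_at_2mm_is_point_eight_ml(self):
        mask = np.zeros((10, 10, 10), np.uint8)
        mask.ravel()[:100] = 1
        tm = tumor_metrics(mask, np.ones((10, 10, 10)), 2.0)
        assert tm.tmtv_ml == pytest.approx(0.8)

    def test_suvmax_over_constant_region(self):
        mask = np.zeros((6, 6, 6), np.uint8); mask[2:4, 2:4, 2:4] = 1
        suv = np.where(mask, 4.2, 1.0)
        assert tumor_metrics(mask, suv, 2.0).suv_max == pytest.approx(4.2)

    def test_two_disjoint_lesions_counted_and_summed(self):
        mask = np.zeros((12, 12, 12), np.uint8)
        mask.ravel()[:10] = 1        # 10-voxel run in the first slice
        mask[8, 5:7, 2:7] = 1        # 10 voxels, disjoint from the first run
        tm = tumor_metrics(mask, np.ones((12, 12, 12)), 2.0)
        assert tm.n_lesions == 2
        assert tm.tmtv_ml == pytest.approx(0.16)
        assert tm.tmtv_ml == pytest.approx(sum(l.volume_ml
                                               for l in tm.per_lesion))

    def test_empty_mask_reports_null_suvmax(self):
        tm = tumor_metrics(np.zeros((4, 4, 4)), np.ones((4, 4, 4)), 2.0)
        assert tm.tmtv_ml == 0.0 and tm.suv_max is None and tm.n_lesions == 0

    @given(st.integers(0, 2 ** 20))
    @settings(max_examples=25, deadline=None)
    def test_tmtv_additive_over_disjoint_masks(self, seed):
        rng = np.random.default_rng(seed)
        a = np.zeros((8, 8, 8), np.uint8)
        b = np.zeros((8, 8, 8), np.uint8)
        a[:4] = rng.random((4, 8, 8)) > 0.7
        b[4:] = rng.random((4, 8, 8)) > 0.7
        suv = rng.random((8, 8, 8)) + 1.0
        tma = tumor_metrics(a, suv, 2.0)
        tmb = tumor_metrics(b, suv, 2.0)
        tmab = tumor_metrics(a | b, suv, 2.0)
        assert tmab.tmtv_ml == pytest.approx(tma.tmtv_ml + tmb.tmtv_ml)
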