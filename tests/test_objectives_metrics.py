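"""Loss hand cases, metric oracles and symmetry/identity properties."""

import numpy as np
import pytest

from iap_transunet.nn import SGD, Conv2d, ReLU, Sequential, Tensor
from iap_transunet.objectives_metrics import (UndefinedDistanceError,
                                              cross_entropy_loss, dice_loss,
                                              dsc_metric, evaluate_case,
                                              hausdorff, mask_boundary,
                                              soft_dice_loss_logits,
                                              softmax_cross_entropy_logits,
                                              total_loss, total_loss_logits)

from oracles import hausdorff_oracle


def _softmax(x, axis=1):
    e = np.exp(x - x.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


class TestCrossEntropy:
    def test_one_hot_prediction_is_near_zero(self):
        y = np.array([[[0, 1], [2, 3]]])
        p = np.moveaxis(np.eye(4)[y], -1, 1)
        assert cross_entropy_loss(p, y) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_over_four_classes_is_ln4(self):
        p = np.full((1, 4, 3, 3), 0.25)
        y = np.zeros((1, 3, 3), dtype=np.int64)
        assert cross_entropy_loss(p, y) == pytest.approx(np.log(4), abs=1e-9)

    def test_hand_mean_of_two_pixels(self):
        # true-class probabilities 0.5 and 0.25 -> (ln2 + ln4)/2
        p = np.zeros((1, 2, 2, 1))
        p[0, :, 0, 0] = [0.5, 0.5]
        p[0, :, 1, 0] = [0.25, 0.75]
        y = np.zeros((1, 2, 1), dtype=np.int64)
        expected = (np.log(2) + np.log(4)) / 2
        assert cross_entropy_loss(p, y) == pytest.approx(expected, abs=1e-9)

    def test_out_of_range_label_rejected(self):
        p = np.full((1, 2, 2, 2), 0.5)
        y = np.full((1, 2, 2), 5, dtype=np.int64)
        with pytest.raises(ValueError, match=r"\[0, 2\)"):
            cross_entropy_loss(p, y)


class TestDiceLoss:
    def test_perfect_one_hot_prediction_is_near_zero(self):
        y = np.array([[[0, 1], [1, 0]]])
        p = np.moveaxis(np.eye(2)[y], -1, 1)
        assert dice_loss(p, y) == pytest.approx(0.0, abs=1e-4)

    def test_fully_disjoint_hard_prediction_approaches_one(self):
        y = np.zeros((1, 4, 4), dtype=np.int64)
        p = np.zeros((1, 2, 4, 4))
        p[:, 1] = 1.0                   # predicts class 1 everywhere, truth 0
        assert dice_loss(p, y) == pytest.approx(1.0, abs=1e-4)

    def test_hand_case_overlap_two_of_four(self):
        # foreground: |X| = 4, |Y| = 4, overlap 2 -> 1 - 2*2/8 = 0.5
        y = np.zeros((1, 4, 4), dtype=np.int64)
        y[0, 0, :4] = 1
        pred = np.zeros((1, 4, 4), dtype=np.int64)
        pred[0, 0, 2:4] = 1
        pred[0, 1, 0:2] = 1
        p = np.moveaxis(np.eye(2)[pred], -1, 1)
        assert dice_loss(p, y, include_background=False) == \
            pytest.approx(0.5, abs=1e-4)

    def test_complement_identity_with_soft_coefficient(self, rng):
        logits = rng.standard_normal((2, 3, 6, 6))
        y = rng.integers(0, 3, (2, 6, 6))
        p = _softmax(logits)
        oh = np.moveaxis(np.eye(3)[y], -1, 1)
        inter = (p * oh).sum(axis=(0, 2, 3))
        denom = p.sum(axis=(0, 2, 3)) + oh.sum(axis=(0, 2, 3))
        soft_dice = ((2 * inter + 1e-5) / (denom + 1e-5)).mean()
        assert dice_loss(p, y) + soft_dice == pytest.approx(1.0, abs=1e-10)


class TestTotalLoss:
    def test_equals_half_sum_of_components(self, rng):
        p = _softmax(rng.standard_normal((2, 4, 5, 5)))
        y = rng.integers(0, 4, (2, 5, 5))
        expected = 0.5 * (cross_entropy_loss(p, y) + dice_loss(p, y))
        assert total_loss(p, y) == pytest.approx(expected, rel=1e-12)

    def test_perfect_prediction_is_near_zero(self):
        y = np.array([[[0, 1], [1, 0]]])
        p = np.clip(np.moveaxis(np.eye(2)[y], -1, 1), 1e-7, 1 - 1e-7)
        assert total_loss(p, y) == pytest.approx(0.0, abs=1e-3)

    def test_logits_path_agrees_with_probability_path(self, rng):
        logits = rng.standard_normal((2, 4, 6, 6)).astype(np.float32)
        y = rng.integers(0, 4, (2, 6, 6))
        via_tensor = total_loss_logits(Tensor(logits), y).item()
        via_numpy = total_loss(_softmax(logits.astype(np.float64)), y)
        assert via_tensor == pytest.approx(via_numpy, abs=1e-5)

    def test_non_increasing_under_small_gradient_steps(self, rng):
        model = Sequential(Conv2d(1, 8, 3, rng=rng), ReLU(),
                           Conv2d(8, 3, 3, rng=rng))
        x = Tensor(rng.standard_normal((2, 1, 12, 12)).astype(np.float32))
        y = rng.integers(0, 3, (2, 12, 12))
        opt = SGD(model.parameters(), lr=1e-3, momentum=0.0)
        losses = []
        for _ in range(50):
            opt.zero_grad()
            loss = total_loss_logits(model(x), y)
            losses.append(loss.item())
            loss.backward()
            opt.step()
        assert losses[-1] < losses[0]
        assert all(b <= a + 1e-4 for a, b in zip(losses, losses[1:]))


class TestDscMetric:
    def test_identical_nonempty_masks_score_one(self):
        m = np.zeros((5, 5), bool)
        m[1:3, 1:4] = True
        assert dsc_metric(m, m) == 1.0

    def test_disjoint_masks_score_zero(self):
        a = np.zeros((5, 5), bool)
        b = np.zeros((5, 5), bool)
        a[0, 0] = True
        b[4, 4] = True
        assert dsc_metric(a, b) == 0.0

    def test_hand_case_half(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, :4] = True                 # |A| = 4
        b[0, 2:4] = True                # overlap 2
        b[1, 0:2] = True                # |B| = 4
        assert dsc_metric(a, b) == 0.5

    def test_empty_conventions(self):
        e = np.zeros((3, 3), bool)
        f = np.zeros((3, 3), bool)
        f[1, 1] = True
        assert dsc_metric(e, e) == 1.0
        assert dsc_metric(e, f) == 0.0

    def test_symmetry_on_random_masks(self, rng):
        for _ in range(20):
            a = rng.random((8, 8)) > 0.6
            b = rng.random((8, 8)) > 0.6
            assert dsc_metric(a, b) == dsc_metric(b, a)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            dsc_metric(np.zeros((2, 2), bool), np.zeros((3, 3), bool))


class TestHausdorff:
    def test_identical_sets_distance_zero(self):
        pts = np.array([[0, 0], [2, 3], [5, 1]])
        assert hausdorff(pts, pts) == 0.0

    def test_single_pair_euclidean(self):
        assert hausdorff(np.array([[0, 0]]), np.array([[3, 4]])) == 5.0

    def test_empty_set_raises(self):
        with pytest.raises(UndefinedDistanceError):
            hausdorff(np.empty((0, 2)), np.array([[1, 1]]))

    def test_matches_double_loop_oracle_exactly(self, rng):
        for _ in range(100):
            a = rng.integers(0, 40, (int(rng.integers(1, 200)), 2))
            b = rng.integers(0, 40, (int(rng.integers(1, 200)), 2))
            assert hausdorff(a, b) == hausdorff_oracle(a, b)
            assert hausdorff(a, b) == hausdorff(b, a)

    def test_boundary_extraction_preserves_mask_hausdorff(self, rng):
        # interior points never attain the max-min, so boundary sets give
        # the same distance as full foreground sets
        for _ in range(10):
            a = np.zeros((16, 16), bool)
            b = np.zeros((16, 16), bool)
            ay, ax = rng.integers(2, 8, 2)
            by, bx = rng.integers(2, 8, 2)
            a[ay:ay + 6, ax:ax + 5] = True
            b[by:by + 4, bx:bx + 7] = True
            full = hausdorff(np.argwhere(a), np.argwhere(b))
            bound = hausdorff(mask_boundary(a), mask_boundary(b))
            assert bound == pytest.approx(full)


class TestEvaluateCase:
    def test_perfect_prediction(self):
        ref = np.zeros((8, 8), dtype=np.int64)
        ref[2:5, 2:5] = 1
        report = evaluate_case(ref, ref, 2)
        assert report.mean_dsc == 1.0
        assert report.class_hd[1] == 0.0
        assert report.n_undefined_hd == 0

    def test_missing_foreground_prediction_is_undefined_hd(self):
        ref = np.zeros((8, 8), dtype=np.int64)
        ref[2:5, 2:5] = 1
        pred = np.zeros_like(ref)
        report = evaluate_case(pred, ref, 2)
        assert report.class_dsc[1] == 0.0
        assert not report.hd_defined[1]
        assert report.n_undefined_hd == 1
        assert np.isnan(report.mean_hd)

    def test_hand_drawn_two_class_fixture(self):
        # class 1: pred is ref shifted right by 2 -> DSC 2*2/(4+4), HD 2
        ref = np.zeros((8, 8), dtype=np.int64)
        pred = np.zeros((8, 8), dtype=np.int64)
        ref[1, 0:4] = 1
        pred[1, 2:6] = 1
        ref[6, 6] = 0
        report = evaluate_case(pred, ref, 2)
        assert report.class_dsc[1] == pytest.approx(0.5)
        assert report.class_hd[1] == pytest.approx(2.0)
        assert report.mean_dsc == pytest.approx(0.5)

    def test_report_serialisation_round_trip(self):
        ref = np.zeros((6, 6), dtype=np.int64)
        ref[1:3, 1:3] = 1
        report = evaluate_case(ref, ref, 2)
        d = report.to_dict()
        assert d["mean_dsc"] == 1.0
        rows = report.rows("case_0000")
        assert len(rows) == 2
        assert rows[1]["hd_defined"] is True
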