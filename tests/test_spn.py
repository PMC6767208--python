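import numpy as np
import pytest

from floorgait.dataset import StepBox
from floorgait.spn import (
    NEGATIVE,
    NEUTRAL,
    POSITIVE,
    AnchorGrid,
    StepProposalNetwork,
    assign_anchors,
    average_precision,
    box_iou,
    decode_boxes,
    iou,
    spn_forward,
    spn_loss,
    spn_loss_grad,
    train_spn,
)
from floorgait.stepdict import EmbeddedSignal
from floorgait.train import TrainConfig


def brute_iou(a: StepBox, b: StepBox) -> float:
    """Count shared and total integer samples explicitly."""
    sa, sb = set(range(a.start, a.end)), set(range(b.start, b.end))
    return len(sa & sb) / len(sa | sb)


class TestIoU:
    def test_identical_boxes(self):
        assert iou(StepBox(0, 20), [StepBox(0, 20)]) == 1.0

    def test_disjoint_boxes(self):
        assert iou(StepBox(0, 20), [StepBox(30, 50)]) == 0.0

    def test_partial_overlap_max_over_gt(self):
        v = iou(StepBox(0, 20), [StepBox(10, 30), StepBox(100, 140)])
        assert v == pytest.approx(10 / 30)

    def test_empty_ground_truth(self):
        assert iou(StepBox(5, 10), []) == 0.0

    def test_matches_brute_force_on_random_boxes(self, rng):
        for _ in range(200):
            a = StepBox(int(rng.integers(0, 50)), int(rng.integers(51, 100)))
            b = StepBox(int(rng.integers(0, 50)), int(rng.integers(51, 100)))
            assert box_iou(a, b) == pytest.approx(brute_iou(a, b))
            assert box_iou(a, b) == box_iou(b, a)
            assert 0.0 <= box_iou(a, b) <= 1.0
            assert (box_iou(a, b) == 1.0) == (a == b)


class TestAnchorGrid:
    @pytest.mark.parametrize("t,expected", [(1000, 95), (60, 1), (1001, 95), (69, 1)])
    def test_feature_len(self, t, expected):
        assert AnchorGrid(t).feature_len == expected

    def test_anchor_coordinates(self):
        g = AnchorGrid(1000)
        assert g.anchor(0, 0) == StepBox(0, 20)
        assert g.anchor(3, 2) == StepBox(30, 70)


class TestAssignAnchors:
    def test_thresholds(self):
        g = AnchorGrid(200)
        # gt exactly on an anchor: that anchor is positive (iou 1 > 0.7)
        labels = assign_anchors(g, [StepBox(30, 60)])
        assert labels[3, 1] == POSITIVE
        # iou 0.75 > 0.7 is positive: anchor [30,60) vs gt [35,60)+[30,65) style
        labels = assign_anchors(g, [StepBox(30, 55)])  # anchor k=1 at i=3: 25/30
        assert labels[3, 1] == POSITIVE

    def test_one_third_iou_is_neutral(self):
        g = AnchorGrid(200)
        # anchor [0,20) vs gt [10,30): iou 10/30 = 0.333 -> neutral
        labels = assign_anchors(g, [StepBox(10, 30)])
        assert labels[0, 0] == NEUTRAL

    def test_empty_gt_all_negative(self):
        labels = assign_anchors(AnchorGrid(300), [])
        assert np.all(labels == NEGATIVE)

    def test_every_anchor_labeled_exactly_once(self, rng):
        g = AnchorGrid(500)
        gt = [StepBox(50, 80), StepBox(200, 230)]
        labels = assign_anchors(g, gt)
        assert set(np.unique(labels)) <= {POSITIVE, NEGATIVE, NEUTRAL}
        assert labels.shape == (g.feature_len, 3)


class TestForward:
    def test_score_map_shape_and_range(self, rng):
        net = StepProposalNetwork(seed=0)
        w = spn_forward(rng.standard_normal((3, 1000)), net)
        assert w.shape == (95, 3)
        assert np.all((w > 0) & (w < 1))

    def test_minimal_input(self, rng):
        net = StepProposalNetwork(seed=0)
        assert spn_forward(rng.standard_normal((3, 60)), net).shape == (1, 3)

    def test_zero_input_gives_half(self):
        net = StepProposalNetwork(seed=1)
        w = spn_forward(np.zeros((3, 200)), net)
        np.testing.assert_allclose(w, 0.5, atol=1e-12)

    def test_short_input_rejected(self):
        net = StepProposalNetwork(seed=0)
        with pytest.raises(ValueError):
            spn_forward(np.zeros((3, 59)), net)

    def test_shift_by_stride_shifts_scores(self, rng):
        net = StepProposalNetwork(seed=2)
        x = np.zeros((3, 500))
        x[:, 200:260] = rng.standard_normal((3, 60))
        w1 = spn_forward(x, net)
        w2 = spn_forward(np.roll(x, 10, axis=1), net)
        np.testing.assert_allclose(w1[10:-12], w2[11:-11], atol=1e-9)


class TestLoss:
    def test_perfect_prediction_near_zero(self):
        w = np.full((4, 3), 0.5)
        labels = np.zeros((4, 3), dtype=np.int8)
        w[0, 0], labels[0, 0] = 1.0 - 1e-9, POSITIVE
        w[1, 1], labels[1, 1] = 1e-9, NEGATIVE
        assert spn_loss(w, labels) == pytest.approx(0.0, abs=1e-5)

    def test_single_positive_at_half(self):
        w = np.full((1, 3), 0.5)
        labels = np.array([[POSITIVE, NEUTRAL, NEUTRAL]], dtype=np.int8)
        assert spn_loss(w, labels) == pytest.approx(np.log(2), rel=1e-6)

    def test_all_neutral_zero_loss_and_grad(self, rng):
        w = rng.random((6, 3))
        labels = np.zeros((6, 3), dtype=np.int8)
        loss, grad = spn_loss_grad(w, labels)
        assert loss == 0.0
        assert np.all(grad == 0.0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            spn_loss(np.zeros((3, 3)), np.zeros((4, 3), dtype=np.int8))


class TestDecodeBoxes:
    def test_no_scores_above_threshold(self):
        assert decode_boxes(np.zeros((10, 3)), AnchorGrid(150)) == []

    def test_single_hot_anchor(self):
        w = np.zeros((10, 3))
        w[4, 2] = 0.9
        out = decode_boxes(w, AnchorGrid(150))
        assert out == [(StepBox(40, 80), 0.9)]

    def test_greedy_suppression(self):
        w = np.zeros((10, 3))
        w[2, 2] = 0.9  # [20, 60)
        w[3, 1] = 0.8  # [30, 60): iou 30/40 = 0.75 > 0.5 -> suppressed
        out = decode_boxes(w, AnchorGrid(150), nms_iou=0.5)
        assert out == [(StepBox(20, 60), 0.9)]


def brute_force_ap(preds, gts, thresh):
    """Enumerate the ranked list, matching greedily, and integrate the
    interpolated precision-recall curve step by step."""
    pool = sorted(
        [(s, i, b) for i, ps in enumerate(preds) for b, s in ps],
        key=lambda p: (-p[0], p[1], p[2].start),
    )
    used = [set() for _ in gts]
    flags = []
    for _, i, b in pool:
        best, bj = 0.0, -1
        for j, g in enumerate(gts[i]):
            if j in used[i]:
                continue
            v = brute_iou(b, g)
            if v > best:
                best, bj = v, j
        if bj >= 0 and best >= thresh:
            used[i].add(bj)
            flags.append(1)
        else:
            flags.append(0)
    n_gt = sum(len(g) for g in gts)
    ap, prev_r, tp = 0.0, 0.0, 0
    pr = []
    for k, f in enumerate(flags, 1):
        tp += f
        pr.append((tp / n_gt, tp / k))
    for idx, (r, _) in enumerate(pr):
        if r > prev_r:
            p_max = max(p for rr, p in pr[idx:])
            ap += (r - prev_r) * p_max
            prev_r = r
    return ap


class TestAveragePrecision:
    def test_perfect_detection(self):
        gts = [[StepBox(0, 20), StepBox(50, 70)]]
        preds = [[(StepBox(0, 20), 0.9), (StepBox(50, 70), 0.8)]]
        assert average_precision(preds, gts, 0.5) == 1.0

    def test_no_matches(self):
        gts = [[StepBox(0, 20)]]
        preds = [[(StepBox(100, 120), 0.9)]]
        assert average_precision(preds, gts, 0.5) == 0.0

    def test_tp_fp_tp_sequence(self):
        gts = [[StepBox(0, 20), StepBox(100, 120)]]
        preds = [[(StepBox(0, 20), 0.9), (StepBox(50, 70), 0.8),
                  (StepBox(100, 120), 0.7)]]
        assert average_precision(preds, gts, 0.5) == pytest.approx(1 / 2 + (2 / 3) / 2)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(100):
            n_sig = int(rng.integers(1, 3))
            gts, preds = [], []
            for _ in range(n_sig):
                gts.append([StepBox(int(s), int(s) + int(rng.integers(10, 40)))
                            for s in rng.integers(0, 200, rng.integers(1, 4)) * 1])
                preds.append([(StepBox(int(s), int(s) + int(rng.integers(10, 40))),
                               float(rng.random()))
                              for s in rng.integers(0, 200, rng.integers(0, 6)) * 1])
            thresh = float(rng.uniform(0.2, 0.9))
            if sum(len(g) for g in gts) == 0:
                continue
            assert average_precision(preds, gts, thresh) == pytest.approx(
                brute_force_ap(preds, gts, thresh)
            )

    def test_no_gt_rejected(self):
        with pytest.raises(ValueError):
            average_precision([[]], [[]], 0.5)


class TestTraining:
    def _toy_walks(self, rng, n=8):
        walks = []
        for i in range(n):
            x = 0.05 * rng.standard_normal((3, 400))
            boxes = []
            for t0 in range(40, 340, 60):
                width = int(rng.integers(25, 35))
                x[:, t0 : t0 + width] += np.hanning(width)[None, :]
                boxes.append(StepBox(t0, t0 + width))
            walks.append((EmbeddedSignal(x, source_id=f"w{i}"), boxes))
        return walks

    def test_seeded_training_is_bitwise_deterministic(self, rng):
        walks = self._toy_walks(rng)
        cfg = TrainConfig(max_epochs=4, patience=10)
        n1 = train_spn(walks, cfg, seed=5)
        n2 = train_spn(walks, cfg, seed=5)
        for k, v in n1.state_dict().items():
            np.testing.assert_array_equal(v, n2.state_dict()[k], err_msg=k)

    def test_signal_without_positive_anchor_skipped(self, rng):
        walks = self._toy_walks(rng, n=3)
        bad = (EmbeddedSignal(0.01 * rng.standard_normal((3, 400))), [StepBox(0, 3)])
        cfg = TrainConfig(max_epochs=2, patience=5)
        with pytest.warns(UserWarning):
            train_spn(walks + [bad], cfg, seed=0)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_spn([], TrainConfig(max_epochs=1))
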