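"""Detection metrics, profiling, and Grad-CAM."""

import numpy as np
import pytest

from lesiondetr import nn
from lesiondetr.nn.tensor import Tensor
from lesiondetr.metrics_xai import (
    IOU_GRID,
    average_precision,
    box_iou,
    evaluate,
    grad_cam,
    match_detections,
    profile,
)


class TestBoxIoU:
    def test_closed_forms(self):
        assert box_iou((0, 0, 2, 2), (0, 0, 2, 2)) == 1.0
        assert box_iou((0, 0, 1, 1), (5, 5, 6, 6)) == 0.0
        assert box_iou((0, 0, 2, 2), (1, 1, 3, 3)) == pytest.approx(1 / 7)

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            box_iou((2, 0, 2, 2), (0, 0, 1, 1))


class TestMatching:
    def test_exact_hit(self):
        tp, fn = match_detections(
            np.array([[0, 0, 10, 10.0]]), np.array([0]),
            np.array([[0, 0, 10, 10.0]]), np.array([0]), 0.5,
        )
        assert tp.tolist() == [True] and fn == 0

    def test_one_match_per_ground_truth(self):
        tp, fn = match_detections(
            np.array([[0, 0, 10, 10.0], [0, 0, 10, 10.0]]), np.array([0, 0]),
            np.array([[0, 0, 10, 10.0]]), np.array([0]), 0.5,
        )
        assert tp.tolist() == [True, False] and fn == 0

    def test_matches_independent_greedy_reimplementation(self, rng):
        """Randomized instances agree with an explicit greedy oracle."""
        for _ in range(20):
            dets = rng.uniform(0, 50, (5, 2))
            det_boxes = np.column_stack([dets, dets + rng.uniform(5, 20, (5, 2))])
            gts = rng.uniform(0, 50, (3, 2))
            gt_boxes = np.column_stack([gts, gts + rng.uniform(5, 20, (3, 2))])
            det_cls = rng.integers(0, 2, 5)
            gt_cls = rng.integers(0, 2, 3)
            tp, fn = match_detections(det_boxes, det_cls, gt_boxes, gt_cls, 0.3)
            # oracle: explicit loop in detection order
            taken = [False] * 3
            expect = []
            for i in range(5):
                best, best_iou = None, 0.3
                for j in range(3):
                    if taken[j] or gt_cls[j] != det_cls[i]:
                        continue
                    v = box_iou(det_boxes[i], gt_boxes[j])
                    if v >= best_iou:
                        best, best_iou = j, v
                if best is None:
                    expect.append(False)
                else:
                    taken[best] = True
                    expect.append(True)
            assert tp.tolist() == expect
            assert fn == 3 - sum(taken)


class TestAveragePrecision:
    def test_perfect_detector_scores_one(self):
        assert average_precision(np.array([1, 1, 1], bool), np.array([0.9, 0.8, 0.7]), 3) == 1.0

    def test_no_detections_with_ground_truth_is_zero(self):
        assert average_precision(np.zeros(0, bool), np.zeros(0), 4) == 0.0

    def test_no_ground_truth_cases(self):
        assert average_precision(np.zeros(0, bool), np.zeros(0), 0) is None
        assert average_precision(np.array([False]), np.array([0.5]), 0) == 0.0

    def test_hand_integrated_three_detection_case(self):
        """TP,FP,TP at scores .9,.8,.7 with 2 gts: precision envelope is 1.0
        up to recall .5 and 2/3 beyond, so the 101-point mean is
        (51*1 + 50*2/3)/101."""
        ap = average_precision(
            np.array([True, False, True]), np.array([0.9, 0.8, 0.7]), 2
        )
        expect = (51 * 1.0 + 50 * (2 / 3)) / 101
        assert ap == pytest.approx(expect, abs=1e-12)

    def test_invariant_to_monotone_score_rescaling(self, rng):
        flags = rng.random(10) < 0.5
        scores = rng.random(10)
        a = average_precision(flags, scores, 6)
        b = average_precision(flags, scores * 100 + 3, 6)
        assert a == b

    def test_appending_lowest_score_miss_never_raises_ap(self, rng):
        flags = rng.random(8) < 0.6
        scores = np.sort(rng.random(8))[::-1]
        base = average_precision(flags, scores, 5)
        worse = average_precision(
            np.append(flags, False), np.append(scores, scores.min() - 0.1), 5
        )
        assert worse <= base + 1e-12


class TestEvaluate:
    def _perfect(self, gts):
        return [
            {"boxes": g["boxes"], "scores": np.ones(len(g["classes"])), "classes": g["classes"]}
            for g in gts
        ]

    def test_perfect_detector_all_metrics_one(self):
        rng = np.random.default_rng(0)
        gts = []
        for _ in range(20):
            tl = rng.uniform(0, 40, (2, 2))
            gts.append(
                {
                    "boxes": np.column_stack([tl, tl + rng.uniform(10, 30, (2, 2))]),
                    "classes": rng.integers(0, 4, 2),
                }
            )
        res = evaluate(self._perfect(gts), gts, classes=[0, 1, 2, 3])
        assert res.map50 == 1.0 and res.map50_95 == 1.0
        for c, ap in res.precision.items():
            if any((g["classes"] == c).any() for g in gts):
                assert res.precision[c] == 1.0 and res.recall[c] == 1.0

    def test_precision_recall_arithmetic(self):
        # one image: 2 TPs, 1 spurious FP, 2 missed gts
        gts = [
            {
                "boxes": np.array(
                    [[0, 0, 10, 10], [20, 20, 30, 30], [40, 40, 50, 50], [60, 60, 70, 70]],
                    dtype=float,
                ),
                "classes": np.array([0, 0, 0, 0]),
            }
        ]
        dets = [
            {
                "boxes": np.array(
                    [[0, 0, 10, 10], [20, 20, 30, 30], [80, 80, 90, 90]], dtype=float
                ),
                "scores": np.array([0.9, 0.8, 0.7]),
                "classes": np.array([0, 0, 0]),
            }
        ]
        res = evaluate(dets, gts, classes=[0])
        assert res.precision[0] == pytest.approx(2 / 3)
        assert res.recall[0] == pytest.approx(1 / 2)

    def test_constructed_iou_062_sweeps_three_thresholds(self):
        """Every detection overlaps its gt at IoU = 0.62 exactly, so AP is 1
        at thresholds 0.50-0.60 and 0 at 0.65+, giving mAP@50-95 = 0.3."""
        # axis-aligned construction: gt (0,0,w,1), det (a,0,w+a,1) has
        # IoU = (w-a)/(w+a); solve (w-a)/(w+a) = 0.62 with w = 81 -> a = 19
        w, a = 81.0, 19.0
        assert (w - a) / (w + a) == pytest.approx(0.62)
        gts, dets = [], []
        for i in range(10):
            gts.append(
                {"boxes": np.array([[0.0, 0, w, 1]]), "classes": np.array([0])}
            )
            dets.append(
                {
                    "boxes": np.array([[a, 0, w + a, 1]]),
                    "scores": np.array([0.9]),
                    "classes": np.array([0]),
                }
            )
        res = evaluate(dets, gts, classes=[0])
        assert res.map50 == 1.0
        assert res.ap[0][0.60] == 1.0 and res.ap[0][0.65] == 0.0
        assert res.map50_95 == pytest.approx(0.3)

    def test_unknown_class_id_rejected(self):
        gts = [{"boxes": np.array([[0, 0, 5, 5.0]]), "classes": np.array([9])}]
        dets = [{"boxes": np.zeros((0, 4)), "scores": np.zeros(0), "classes": np.zeros(0, int)}]
        with pytest.raises(ValueError, match="class id 9"):
            evaluate(dets, gts, classes=[0, 1])


class TestProfile:
    def test_pointwise_conv_hand_counts(self):
        nn.manual_seed(0)
        layer = nn.Conv2d(4, 8, 1)
        stats = profile(layer, 10, in_channels=4)
        assert stats["params"] == 4 * 8 + 8
        assert stats["macs"] == 4 * 8 * 100
        assert stats["gflops"] == pytest.approx(2 * stats["macs"] / 1e9)

    def test_linear_stack_hand_counts(self):
        nn.manual_seed(0)

        class Toy(nn.Module):
            def __init__(self):
                super().__init__()
                self.a = nn.Conv2d(2, 3, 3, padding=1)
                self.b = nn.Conv2d(3, 5, 1, bias=False)

            def forward(self, x):
                return self.b(self.a(x))

        stats = profile(Toy(), 4, in_channels=2)
        assert stats["params"] == (2 * 3 * 9 + 3) + (3 * 5)
        assert stats["macs"] == 2 * 3 * 9 * 16 + 3 * 5 * 16


class _StubDetector(nn.Module):
    """Minimal detector-shaped model for checking the CAM weighting rule."""

    def __init__(self, activation):
        super().__init__()
        self.act_param = nn.Parameter(activation)  # (1, 1, 2, 2)
        self.target = nn.Identity()

    def forward_raw(self, image):
        act = self.target(self.act_param * 1.0)
        s = act.sum().reshape(1, 1, 1)
        logits = nn.concatenate([s, s * 0.0], axis=-1)  # (1, 1, 2)
        boxes = nn.concatenate([s, s, s, s], axis=-1) * 0.0
        return logits, boxes


class TestGradCAM:
    def test_uniform_gradient_recovers_rectified_activation(self):
        """With d(objective)/d(act) = 1 everywhere, the heatmap is the
        min-max normalization of max(mean_grad * act, 0) = max(act, 0)."""
        act = np.array([[[[1.0, -2.0], [3.0, 0.5]]]])
        model = _StubDetector(act)
        maps = grad_cam(model, np.zeros((2, 2)), ["target"], top_fraction=1.0)
        expect = np.maximum(act[0, 0], 0)
        expect = expect / expect.max()
        np.testing.assert_allclose(maps["target"], expect, atol=1e-6)

    def test_constant_objective_gives_all_zero_heatmap(self):
        from lesiondetr.model_zoo import ModelConfig, build_model

        model = build_model(
            ModelConfig.tiny(seed=0, hidden_dim=16, num_heads=2, num_queries=5,
                             backbone_widths=(8, 12, 16, 20),
                             backbone_depths=(1, 1, 1, 1), decoder_layers=1)
        )
        # freeze the heads at exactly zero output
        for lin in [model.class_head, model.box_head[0], model.box_head[2]]:
            lin.weight.data = np.zeros_like(lin.weight.data)
            lin.bias.data = np.zeros_like(lin.bias.data)
        img = np.random.default_rng(0).random((96, 96))
        maps = grad_cam(model, img, model.default_cam_targets)
        for heat in maps.values():
            np.testing.assert_array_equal(heat, 0)

    def test_heatmap_contract_on_real_model(self):
        from lesiondetr.model_zoo import ModelConfig, build_model

        model = build_model(
            ModelConfig.tiny(seed=1, hidden_dim=16, num_heads=2, num_queries=5,
                             backbone_widths=(8, 12, 16, 20),
                             backbone_depths=(1, 1, 1, 1), decoder_layers=1)
        )
        img = np.random.default_rng(1).random((96, 96))
        maps = grad_cam(model, img, model.default_cam_targets)
        assert set(maps) == set(model.default_cam_targets)
        for heat in maps.values():
            assert heat.shape == img.shape
            assert heat.min() >= 0.0 and heat.max() <= 1.0

    def test_unknown_target_module_rejected(self):
        model = _StubDetector(np.ones((1, 1, 2, 2)))
        with pytest.raises(ValueError, match="unknown target"):
            grad_cam(model, np.zeros((2, 2)), ["nope"])
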