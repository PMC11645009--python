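"""IoU, precision/recall, average precision and the evaluation summary."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sefast.evaluation import (
    ConfusionCounts,
    EvalSummary,
    PredictedBox,
    average_precision,
    evaluate,
    iou,
    precision_recall,
)
from sefast.formats import AVARecord, BoundingBox, LabelMap


class TestIoU:
    def test_identical_boxes(self):
        b = BoundingBox(0.1, 0.2, 0.6, 0.9)
        assert iou(b, b) == pytest.approx(1.0)

    def test_disjoint_boxes(self):
        assert iou(BoundingBox(0.0, 0.0, 0.2, 0.2),
                   BoundingBox(0.5, 0.5, 0.9, 0.9)) == 0.0

    def test_half_overlap_reference(self):
        # unit-ish boxes offset by half a width: intersection 0.5, union 1.5
        a = BoundingBox(0.0, 0.0, 1.0, 1.0)
        b = BoundingBox(0.5, 0.0, 1.0, 1.0)
        wide = BoundingBox(0.0, 0.0, 0.5, 1.0)
        assert iou(a, BoundingBox(0.5, 0.0, 1.0, 1.0)) == pytest.approx(0.5)
        # the classic 1/3 case on a half-shifted equal box
        left = BoundingBox(0.0, 0.0, 0.5, 1.0)
        right = BoundingBox(0.25, 0.0, 0.75, 1.0)
        assert iou(left, right) == pytest.approx(1 / 3)

    @settings(max_examples=100, deadline=None)
    @given(st.data())
    def test_symmetry_and_area_bound(self, data):
        def rand_box():
            x1 = data.draw(st.floats(0, 0.8))
            y1 = data.draw(st.floats(0, 0.8))
            return BoundingBox(x1, y1,
                               x1 + data.draw(st.floats(0.05, 0.2)),
                               y1 + data.draw(st.floats(0.05, 0.2)))

        a, b = rand_box(), rand_box()
        assert iou(a, b) == pytest.approx(iou(b, a))
        assert 0.0 <= iou(a, b) <= min(a.area, b.area) / max(a.area, b.area) + 1e-12


class TestPrecisionRecall:
    def test_reference_arithmetic(self):
        p, r = precision_recall(ConfusionCounts(tp=8, fp=2, fn=4))
        assert p == pytest.approx(0.8)
        assert r == pytest.approx(2 / 3)

    def test_perfect(self):
        assert precision_recall(ConfusionCounts(tp=5)) == (1.0, 1.0)

    def test_zero_tp_with_detections(self):
        p, r = precision_recall(ConfusionCounts(tp=0, fp=3, fn=2))
        assert p == 0.0 and r == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1)


def _brute_force_ap(detections, gts, iou_thr=0.5, grid=20001):
    """Independent AP oracle: greedy matching, then numeric integration of the
    interpolated precision over a dense recall grid."""
    n_gt = sum(len(v) for v in gts.values())
    order = sorted(range(len(detections)), key=lambda i: (-detections[i][0], i))
    taken = set()
    points = []  # (recall, precision) after each detection
    tp = fp = 0
    for i in order:
        _, key, box = detections[i]
        cands = [
            (j, iou(box, g)) for j, g in enumerate(gts.get(key, ()))
            if (key, j) not in taken and iou(box, g) >= iou_thr
        ]
        if cands:
            j = max(cands, key=lambda c: c[1])[0]
            taken.add((key, j))
            tp += 1
        else:
            fp += 1
        points.append((tp / n_gt, tp / (tp + fp)))
    rs = np.linspace(0, 1, grid)[1:]  # integrate p_interp(r) dr, open at 0
    p_interp = np.array([
        max((p for r2, p in points if r2 >= r), default=0.0) for r in rs
    ])
    return float(p_interp.mean())


class TestAveragePrecision:
    def test_perfect_detections(self):
        box = BoundingBox(0.2, 0.2, 0.6, 0.6)
        gts = {("v", s): [box] for s in range(4)}
        dets = [(1.0, ("v", s), box) for s in range(4)]
        assert average_precision(dets, gts) == pytest.approx(1.0)

    def test_no_detections(self):
        assert average_precision([], {("v", 0): [BoundingBox(0, 0, 1, 1)]}) == 0.0

    def test_hand_built_three_detection_curve(self):
        """Scores .9 (TP), .8 (FP), .7 (TP) over 2 GT:
        envelope is p=1 up to r=0.5, then p=2/3 -> AP = 5/6."""
        gt_box1 = BoundingBox(0.1, 0.1, 0.4, 0.4)
        gt_box2 = BoundingBox(0.6, 0.6, 0.9, 0.9)
        far = BoundingBox(0.05, 0.6, 0.3, 0.9)
        gts = {("v", 0): [gt_box1], ("v", 1): [gt_box2]}
        dets = [(0.9, ("v", 0), gt_box1), (0.8, ("v", 0), far),
                (0.7, ("v", 1), gt_box2)]
        assert average_precision(dets, gts) == pytest.approx(5 / 6)

    def test_monotone_score_transform_invariance(self):
        rng = np.random.default_rng(1)
        gts = {("v", s): [BoundingBox(0.2, 0.2, 0.6, 0.6)] for s in range(5)}
        dets = []
        for s in range(5):
            good = rng.uniform() < 0.6
            box = (BoundingBox(0.2, 0.2, 0.6, 0.6) if good
                   else BoundingBox(0.7, 0.7, 0.95, 0.95))
            dets.append((rng.uniform(0.1, 0.9), ("v", s), box))
        ap1 = average_precision(dets, gts)
        squashed = [(s**3 * 0.5, k, b) for s, k, b in dets]
        assert average_precision(squashed, gts) == pytest.approx(ap1)

    @settings(max_examples=60, deadline=None)
    @given(st.data())
    def test_agrees_with_brute_force_on_small_cases(self, data):
        """All-point AP matches an independent numeric integration for up to
        5 detections over up to 3 ground-truth boxes."""
        anchors = [BoundingBox(0.05, 0.05, 0.3, 0.3),
                   BoundingBox(0.4, 0.4, 0.7, 0.7),
                   BoundingBox(0.72, 0.1, 0.95, 0.35)]
        n_gt = data.draw(st.integers(1, 3))
        gts = {("v", 0): anchors[:n_gt]}
        n_det = data.draw(st.integers(1, 5))
        dets = []
        for i in range(n_det):
            which = data.draw(st.integers(0, 3))
            box = (anchors[which] if which < 3
                   else BoundingBox(0.1, 0.75, 0.35, 0.95))
            score = data.draw(st.sampled_from([0.9, 0.7, 0.5, 0.3, 0.1]))
            dets.append((score, ("v", 0), box))
        got = average_precision(dets, gts)
        want = _brute_force_ap(dets, gts)
        assert got == pytest.approx(want, abs=2e-4)

    def test_random_scores_approach_prevalence(self):
        """Under a permutation null the AP concentrates near the positive
        prevalence among candidate boxes."""
        rng = np.random.default_rng(0)
        pos_box = BoundingBox(0.2, 0.2, 0.6, 0.6)
        neg_box = BoundingBox(0.7, 0.7, 0.95, 0.95)
        n, n_pos = 400, 100
        gts = {("v", s): [pos_box] for s in range(n_pos)}
        aps = []
        for _ in range(40):
            dets = [
                (rng.uniform(), ("v", s), pos_box if s < n_pos else neg_box)
                for s in range(n)
            ]
            aps.append(average_precision(dets, gts))
        prevalence = n_pos / n
        # the precision envelope biases the null slightly above prevalence;
        # the bias shrinks with n and is well under 0.04 at this size
        assert abs(np.mean(aps) - prevalence) < 0.04


class TestEvaluate:
    def _identity_setup(self, labels):
        box = BoundingBox(0.2, 0.2, 0.7, 0.9)
        gts, preds = [], []
        for s in range(6):
            posture = 1 + s % 3
            gts.append(AVARecord("v", s, box, posture, 0))
            scores = [0.0] * 5
            scores[posture - 1] = 1.0
            if posture == 1:
                gts.append(AVARecord("v", s, box, 4, 0))
                scores[3] = 1.0
            preds.append(PredictedBox("v", s, box, tuple(scores)))
        return preds, gts

    def test_identity_predictions_score_perfectly(self, labels):
        preds, gts = self._identity_setup(labels)
        summary = evaluate(preds, gts, labels)
        assert summary.mAP == pytest.approx(1.0)
        for name, m in summary.per_class.items():
            if m.support:
                assert m.accuracy == 1.0 and m.recall == 1.0

    def test_map_averages_only_supported_classes(self, labels):
        preds, gts = self._identity_setup(labels)  # Sleeping never occurs
        summary = evaluate(preds, gts, labels)
        assert summary.per_class["Sleeping"].support == 0
        supported = [m.ap for m in summary.per_class.values() if m.support]
        assert summary.mAP == pytest.approx(np.mean(supported))

    def test_class_independence(self, labels):
        """Zeroing one class's scores leaves the other classes' APs unchanged."""
        preds, gts = self._identity_setup(labels)
        summary = evaluate(preds, gts, labels)
        zeroed = [
            PredictedBox(p.video_id, p.timestamp_s, p.box,
                         tuple(0.0 if i == 0 else v for i, v in enumerate(p.scores)))
            for p in preds
        ]
        summary2 = evaluate(zeroed, gts, labels)
        for name in ("Sternal recumbency", "Lateral recumbency", "Eating"):
            assert summary2.per_class[name].ap == pytest.approx(
                summary.per_class[name].ap)
        assert summary2.per_class["Standing"].recall == 0.0

    def test_empty_ground_truth_rejected(self, labels):
        with pytest.raises(ValueError):
            evaluate([], [], labels)

    def test_empty_predictions_zero_map(self, labels):
        _, gts = self._identity_setup(labels)
        summary = evaluate([], gts, labels)
        assert summary.mAP == 0.0


class TestCompareLosses:
    def test_single_cell_contract_and_determinism(self, small_corpus):
        from sefast.evaluation import compare_losses
        from sefast.network import NetConfig

        kw = dict(losses=("cw_f",), r_values=(2,), placements=("end",),
                  seeds=(0,), epochs=1)
        table = compare_losses(small_corpus, NetConfig.tiny(), **kw)
        assert len(table) == 1
        row = table.iloc[0]
        metric_cols = [c for c in table.columns if c.startswith(("ap_", "acc_", "recall_"))]
        assert metric_cols
        for col in metric_cols + ["mAP", "minority_posture_recall"]:
            assert 0.0 <= row[col] <= 1.0
        again = compare_losses(small_corpus, NetConfig.tiny(), **kw)
        assert np.allclose(table[metric_cols].values, again[metric_cols].values)

    def test_resumable_cache(self, small_corpus, tmp_path):
        from sefast.evaluation import compare_losses
        from sefast.network import NetConfig

        kw = dict(losses=("cw_f",), r_values=(2,), placements=("end",),
                  seeds=(0,), epochs=1, out_dir=tmp_path)
        t1 = compare_losses(small_corpus, NetConfig.tiny(), **kw)
        assert len(list(tmp_path.glob("*.json"))) == 1
        t2 = compare_losses(small_corpus, NetConfig.tiny(), **kw)
        assert t1.equals(t2)


class TestLossComparisonDirection:
    def test_class_weighting_helps_minority_recall(self, comparison_runs, labels):
        """Scaled-down analogue of the loss comparison: with the reference
        imbalance, the class-weighted focal loss should not trail plain
        focal BCE on minority-posture recall (median over 3 seeds)."""
        cw = np.median([r["summary"].minority_posture_recall(labels)
                        for r in comparison_runs["cw_f"]])
        bce = np.median([r["summary"].minority_posture_recall(labels)
                         for r in comparison_runs["bce_f"]])
        assert cw >= bce
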