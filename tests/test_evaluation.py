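"""Mask-matched average precision and its building blocks."""

import numpy as np
import pytest

from hcpl.evaluation import (average_precision, mask_iou, match_cells,
                             mean_ap, score_matched)


class TestMaskIoU:
    def test_identical_masks(self):
        m = np.zeros((4, 4), dtype=bool)
        m[1:3, 1:3] = True
        assert mask_iou(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4), dtype=bool)
        b = np.zeros((4, 4), dtype=bool)
        a[0, 0] = True
        b[3, 3] = True
        assert mask_iou(a, b) == 0.0

    def test_partial_overlap_closed_form(self):
        # two 2x4 rectangles overlapping in a 2x2 region: IoU = 4/12
        a = np.zeros((4, 8), dtype=bool)
        b = np.zeros((4, 8), dtype=bool)
        a[0:2, 0:4] = True
        b[0:2, 2:6] = True
        assert mask_iou(a, b) == pytest.approx(1 / 3)

    def test_empty_union_is_zero(self):
        z = np.zeros((3, 3), dtype=bool)
        assert mask_iou(z, z) == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mask_iou(np.zeros((2, 2), dtype=bool), np.zeros((3, 3), dtype=bool))


def _blob(h, w, r0, r1, c0, c1):
    m = np.zeros((h, w), dtype=bool)
    m[r0:r1, c0:c1] = True
    return m


class TestMatchCells:
    def test_perfect_predictions_all_matched(self):
        gts = [_blob(10, 10, 0, 4, 0, 4), _blob(10, 10, 6, 10, 6, 10)]
        res = match_cells(gts, np.array([0.9, 0.8]), gts)
        assert len(res.pairs) == 2
        assert res.unmatched_predictions == []
        assert res.unmatched_ground_truths == []
        assert all(iou > 0.6 for _, _, iou in res.pairs)

    def test_no_overlap_leaves_everything_unmatched(self):
        pred = [_blob(10, 10, 0, 2, 0, 2)]
        gts = [_blob(10, 10, 5, 7, 5, 7), _blob(10, 10, 8, 10, 8, 10)]
        res = match_cells(pred, np.array([0.9]), gts)
        assert res.pairs == []
        assert res.unmatched_predictions == [0]
        assert len(res.unmatched_ground_truths) == 2

    def test_ground_truth_matched_at_most_once(self):
        gt = [_blob(10, 10, 0, 5, 0, 5)]
        preds = [gt[0], gt[0]]
        res = match_cells(preds, np.array([0.9, 0.8]), gt)
        assert len(res.pairs) == 1
        assert res.pairs[0][0] == 0  # the higher-confidence prediction wins
        assert res.unmatched_predictions == [1]

    def test_matches_independent_greedy_oracle(self, rng):
        # randomised small instances vs a naive re-implementation
        for trial in range(20):
            rng_t = np.random.default_rng(trial)
            h = w = 24
            def rand_masks(n):
                out = []
                for _ in range(n):
                    r = rng_t.integers(0, h - 6)
                    c = rng_t.integers(0, w - 6)
                    out.append(_blob(h, w, r, r + 6, c, c + 6))
                return out
            preds = rand_masks(int(rng_t.integers(1, 7)))
            gts = rand_masks(int(rng_t.integers(1, 7)))
            conf = rng_t.uniform(size=len(preds))
            res = match_cells(preds, conf, gts)
            # oracle: explicit loops, same greedy rule
            taken = set()
            expected = []
            for p in sorted(range(len(preds)), key=lambda i: -conf[i]):
                best, best_iou = None, 0.6
                for g in range(len(gts)):
                    if g in taken:
                        continue
                    inter = (preds[p] & gts[g]).sum()
                    union = (preds[p] | gts[g]).sum()
                    iou = inter / union if union else 0.0
                    if iou > best_iou:
                        best, best_iou = g, iou
                if best is not None:
                    taken.add(best)
                    expected.append((p, best))
            assert [(p, g) for p, g, _ in res.pairs] == expected


class TestAveragePrecision:
    def test_single_true_positive(self):
        assert average_precision([(0.9, True)], 1) == 1.0

    def test_tp_then_fp_versus_fp_then_tp(self):
        assert average_precision([(0.9, True), (0.5, False)], 1) == 1.0
        assert average_precision([(0.9, False), (0.5, True)], 1) == 0.5

    def test_no_positives_and_no_detections(self):
        assert average_precision([], 0) == 0.0

    def test_negative_positive_count_rejected(self):
        with pytest.raises(ValueError):
            average_precision([], -1)

    def test_matches_threshold_sweep_oracle(self):
        """All-point AP vs brute-force precision-recall rectangle sum."""
        for trial in range(100):
            rng = np.random.default_rng(trial)
            n = int(rng.integers(1, 51))
            conf = rng.uniform(size=n)  # distinct with probability one
            tp = rng.uniform(size=n) < 0.4
            n_pos = int(tp.sum() + rng.integers(0, 3))
            ap = average_precision(list(zip(conf, tp)), n_pos)
            if n_pos == 0:
                assert ap == 0.0
                continue
            # sweep every threshold, accumulate precision * delta-recall
            expected = 0.0
            last_recall = 0.0
            for t in sorted(set(conf), reverse=True):
                sel = conf >= t
                tp_at = int(tp[sel].sum())
                prec = tp_at / sel.sum()
                recall = tp_at / n_pos
                expected += prec * (recall - last_recall)
                last_recall = recall
            assert abs(ap - expected) < 1e-9

    def test_removing_false_positive_never_decreases_ap(self, rng):
        for trial in range(20):
            rng_t = np.random.default_rng(trial)
            n = int(rng_t.integers(3, 20))
            conf = rng_t.uniform(size=n)
            tp = rng_t.uniform(size=n) < 0.5
            if tp.all():
                tp[0] = False
            n_pos = max(int(tp.sum()), 1)
            dets = list(zip(conf, tp))
            base = average_precision(dets, n_pos)
            fp_idx = next(i for i, (_, t) in enumerate(dets) if not t)
            pruned = dets[:fp_idx] + dets[fp_idx + 1:]
            assert average_precision(pruned, n_pos) >= base - 1e-12


class TestMeanAP:
    def test_constant_vector(self):
        assert mean_ap(np.full(5, 0.7)) == pytest.approx(0.7)

    def test_two_class_example(self):
        assert mean_ap(np.array([1.0, 0.0])) == 0.5

    def test_matches_naive_mean(self, rng):
        v = rng.uniform(size=19)
        assert abs(mean_ap(v) - sum(v) / len(v)) < 1e-12

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            mean_ap(np.array([]))


class TestScoreMatched:
    def test_perfect_prediction_gives_map_one(self, rng):
        labels = (rng.uniform(size=(30, 5)) < 0.4).astype(float)
        labels[:, 0] = 1.0  # ensure every class has a positive somewhere
        labels[0] = 1.0
        result = score_matched(labels, labels)
        assert result.map == 1.0
        assert (result.per_class_ap == 1.0).all()

    def test_map_is_mean_of_per_class(self, rng):
        probs = rng.uniform(size=(20, 4))
        labels = (rng.uniform(size=(20, 4)) < 0.5).astype(float)
        res = score_matched(probs, labels)
        assert res.map == pytest.approx(res.per_class_ap.mean())
        assert ((res.per_class_ap >= 0) & (res.per_class_ap <= 1)).all()
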