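"""Pixel/object metrics against brute-force and hand-computed oracles."""

import itertools

import numpy as np
import pytest

from conftest import random_instance_maps
from nucquant.evalmetrics import (
    ConfusionCounts,
    aji,
    dice_pixel,
    evaluate_patches,
    match_objects,
    object_pr,
    pixel_confusion,
    pixel_metrics,
    roc_pr_curves,
    threshold_sweep,
)


class TestPixelConfusion:
    def test_identical_masks(self):
        gt = np.zeros((10, 10), bool)
        gt[:3] = True
        c = pixel_confusion(gt, gt)
        assert (c.tp, c.fp, c.tn, c.fn) == (30, 0, 70, 0)

    def test_inverted_masks(self):
        gt = np.random.default_rng(0).random((8, 8)) > 0.5
        c = pixel_confusion(~gt, gt)
        assert c.tp == 0 and c.tn == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_tally(self, seed):
        rng = np.random.default_rng(seed)
        pred = rng.random((4, 4)) > 0.5
        gt = rng.random((4, 4)) > 0.5
        c = pixel_confusion(pred, gt)
        tally = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
        for i in range(4):
            for j in range(4):
                key = ("t" if pred[i, j] == gt[i, j] else "f") + \
                      ("p" if pred[i, j] else "n")
                tally[key] += 1
        assert (c.tp, c.fp, c.tn, c.fn) == (tally["tp"], tally["fp"],
                                            tally["tn"], tally["fn"])
        assert c.total == 16


class TestPixelMetrics:
    def test_hand_computed_example(self):
        acc, sen, spe = pixel_metrics(ConfusionCounts(tp=50, fp=5, tn=40, fn=5))
        assert acc == pytest.approx(0.90)
        assert sen == pytest.approx(50 / 55)
        assert spe == pytest.approx(40 / 45)

    def test_perfect_prediction(self):
        assert pixel_metrics(ConfusionCounts(10, 0, 10, 0)) == (1.0, 1.0, 1.0)

    def test_undefined_sensitivity_reported_absent(self):
        acc, sen, spe = pixel_metrics(ConfusionCounts(tp=0, fp=2, tn=8, fn=0))
        assert sen is None and spe is not None

    def test_empty_confusion_rejected(self):
        with pytest.raises(ValueError):
            pixel_metrics(ConfusionCounts(0, 0, 0, 0))


class TestDicePixel:
    def test_identical_and_disjoint(self):
        m = np.zeros((6, 6), bool)
        m[:2] = True
        assert dice_pixel(m, m) == pytest.approx(1.0)
        assert dice_pixel(m, ~m) == pytest.approx(0.0)

    def test_half_overlap_formula(self):
        # tp=2, fp=2, fn=2 -> 4/8
        pred = np.array([[1, 1, 1, 1, 0, 0]], dtype=bool)
        gt = np.array([[1, 1, 0, 0, 1, 1]], dtype=bool)
        assert dice_pixel(pred, gt) == pytest.approx(0.5)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.random((8, 8)) > 0.5, rng.random((8, 8)) > 0.5
        assert dice_pixel(a, b) == dice_pixel(b, a)


def _aji_exhaustive(gt, pred):
    """Best-assignment AJI by enumerating every injective gt->pred matching
    (feasible for <= 4 instances per map)."""
    gt_ids = [int(i) for i in np.unique(gt) if i > 0]
    pred_ids = [int(i) for i in np.unique(pred) if i > 0]
    if not gt_ids and not pred_ids:
        return 1.0
    if not gt_ids:
        return 0.0
    best = 0.0
    options = pred_ids + [None]
    for combo in itertools.product(options, repeat=len(gt_ids)):
        chosen = [c for c in combo if c is not None]
        if len(chosen) != len(set(chosen)):
            continue
        num = den = 0
        for g, p in zip(gt_ids, combo):
            gm = gt == g
            if p is None:
                den += gm.sum()
            else:
                pm = pred == p
                num += (gm & pm).sum()
                den += (gm | pm).sum()
        for p in pred_ids:
            if p not in chosen:
                den += (pred == p).sum()
        if den:
            best = max(best, num / den)
    return best


class TestAJI:
    def test_identical_maps_up_to_relabelling(self):
        gt = np.zeros((8, 8), int)
        gt[0:3, 0:3] = 1
        gt[5:8, 5:8] = 2
        relabelled = np.where(gt == 1, 7, np.where(gt == 2, 3, 0))
        assert aji(gt, relabelled) == pytest.approx(1.0)

    def test_empty_prediction_scores_zero(self):
        gt = np.zeros((4, 4), int)
        gt[:2, :2] = 1
        assert aji(gt, np.zeros_like(gt)) == 0.0

    def test_partial_overlap_one_third(self):
        gt = np.zeros((4, 4), int)
        gt[0:2, 0:2] = 1
        pred = np.zeros((4, 4), int)
        pred[1:3, 0:2] = 1
        assert aji(gt, pred) == pytest.approx(2 / 6)

    def test_unmatched_prediction_penalised(self):
        gt = np.zeros((4, 4), int)
        gt[0:2, 0:2] = 1
        pred = gt.copy()
        pred[3, 1:4] = 2
        assert aji(gt, pred) == pytest.approx(4 / 7)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            aji(np.zeros((3, 3), int), np.zeros((4, 4), int))

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            gt, pred = random_instance_maps(rng)
            assert 0.0 <= aji(gt, pred) <= 1.0

    @pytest.mark.parametrize("seed", range(30))
    def test_greedy_matching_agrees_with_exhaustive_assignment(self, seed):
        """On perturbed-copy fixtures with <= 4 instances the greedy
        per-ground-truth argmax matching attains the exhaustive optimum."""
        rng = np.random.default_rng(seed)
        gt, pred = random_instance_maps(rng, n_gt=int(rng.integers(1, 5)))
        assert aji(gt, pred) == pytest.approx(_aji_exhaustive(gt, pred),
                                              abs=1e-12)


class TestObjectMatching:
    def test_identical_maps_all_matched_at_iou_one(self):
        gt = np.zeros((8, 8), int)
        gt[0:3, 0:3] = 1
        gt[5:8, 5:8] = 2
        m = match_objects(gt, gt, 0.5)
        assert len(m.pairs) == 2
        assert all(iou == pytest.approx(1.0) for _, _, iou in m.pairs)
        assert object_pr(m) == (1.0, 1.0)

    def test_extra_prediction_counts_as_false_positive(self):
        gt = np.zeros((10, 10), int)
        gt[0:3, 0:3] = 1
        gt[0:3, 6:9] = 2
        pred = gt.copy()
        pred[7:9, 7:9] = 3
        m = match_objects(gt, pred, 0.5)
        assert len(m.pairs) == 2 and m.unmatched_pred == [3]
        prec, rec = object_pr(m)
        assert prec == pytest.approx(2 / 3)
        assert rec == pytest.approx(1.0)

    def test_overlap_below_threshold_unmatched(self):
        gt = np.zeros((6, 6), int)
        gt[0:2, 0:2] = 1
        pred = np.zeros((6, 6), int)
        pred[1:3, 1:3] = 1  # IoU = 1/7 < 0.5
        m = match_objects(gt, pred, 0.5)
        assert not m.pairs

    def test_matching_is_one_to_one(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            gt, pred = random_instance_maps(rng)
            m = match_objects(gt, pred, 0.1)
            gs = [g for g, _, _ in m.pairs]
            ps = [p for _, p, _ in m.pairs]
            assert len(gs) == len(set(gs)) and len(ps) == len(set(ps))

    def test_no_predictions_precision_absent(self):
        gt = np.zeros((4, 4), int)
        gt[:2, :2] = 1
        m = match_objects(gt, np.zeros_like(gt), 0.5)
        prec, rec = object_pr(m)
        assert prec is None and rec == 0.0

    def test_recall_non_increasing_in_iou_threshold(self):
        rng = np.random.default_rng(9)
        gt, pred = random_instance_maps(rng, n_gt=4)
        recalls = []
        for thr in (0.1, 0.3, 0.5, 0.7, 0.9):
            _, rec = object_pr(match_objects(gt, pred, thr))
            recalls.append(rec)
        assert all(b <= a for a, b in zip(recalls, recalls[1:]))


class TestCurves:
    def test_perfect_scores_auc_one(self):
        gt = np.random.default_rng(0).random((16, 16)) > 0.5
        _, auc_roc, _, auc_pr = roc_pr_curves([gt.astype(float)], [gt])
        assert auc_roc == pytest.approx(1.0)
        assert auc_pr == pytest.approx(1.0)

    def test_inverted_scores_auc_zero(self):
        gt = np.random.default_rng(1).random((16, 16)) > 0.5
        _, auc_roc, _, _ = roc_pr_curves([1.0 - gt.astype(float)], [gt])
        assert auc_roc == pytest.approx(0.0)

    def test_random_scores_auc_half(self):
        rng = np.random.default_rng(2)
        gt = rng.random((100, 100)) > 0.5
        scores = rng.random((100, 100))
        _, auc_roc, _, _ = roc_pr_curves([scores], [gt])
        assert auc_roc == pytest.approx(0.5, abs=0.02)

    def test_single_class_pool_rejected(self):
        with pytest.raises(ValueError):
            roc_pr_curves([np.zeros((4, 4))], [np.zeros((4, 4), bool)])


class TestThresholdSweep:
    def test_emits_one_row_per_threshold(self, small_patch):
        _, labels = small_patch
        prob = (labels > 0) * 0.9
        sweep = threshold_sweep([prob], [labels])
        assert list(sweep["threshold"]) == [0.30, 0.35, 0.40, 0.45, 0.50]

    def test_perfect_maps_score_one_everywhere(self, small_patch):
        _, labels = small_patch
        prob = (labels > 0).astype(float)
        sweep = threshold_sweep([prob], [labels],
                                thresholds=(0.3, 0.4, 0.5))
        assert (sweep["precision"] == 1.0).all()
        assert (sweep["recall"] == 1.0).all()

    def test_unsorted_thresholds_rejected(self, small_patch):
        _, labels = small_patch
        with pytest.raises(ValueError):
            threshold_sweep([(labels > 0).astype(float)], [labels],
                            thresholds=(0.5, 0.3))


class TestEvaluatePatches:
    def test_pooled_report_on_clean_predictions(self, small_patch):
        _, labels = small_patch
        prob = np.where(labels > 0, 0.95, 0.03)
        report = evaluate_patches([prob], [labels > 0], [labels])
        assert report.acc == pytest.approx(1.0)
        assert report.dice == pytest.approx(1.0)
        assert report.aji == pytest.approx(1.0)
        assert report.precision == 1.0 and report.recall == 1.0
        assert report.auc_roc == pytest.approx(1.0)

    def test_patch_mean_mode_skips_undefined(self):
        prob_fg = np.full((8, 8), 0.9)
        gt_fg = np.ones((8, 8), bool)
        prob_empty = np.zeros((8, 8))
        gt_empty = np.zeros((8, 8), bool)
        report = evaluate_patches([prob_fg, prob_empty], [gt_fg, gt_empty],
                                  mode="patch_mean")
        # specificity undefined on the all-fg patch, sensitivity on the empty
        assert report.n_undefined["sen"] == 1
        assert report.n_undefined["spe"] == 1
        assert report.sen == pytest.approx(1.0)
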