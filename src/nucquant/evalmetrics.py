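"""Pixel- and object-level segmentation evaluation.

Pixel level: confusion counts, accuracy / sensitivity / specificity, Dice,
pooled ROC and precision-recall curves with trapezoidal AUC.  Object level:
the aggregated Jaccard index (AJI), one-to-one IoU matching of instances,
precision/recall, and the threshold sweep that re-runs the post-processing
chain per probability threshold.

Zero-denominator rule used throughout: a metric whose denominator is empty
(e.g. sensitivity on a patch with no foreground) is reported as ``None`` —
absent, not 0 or 1 — and excluded from aggregate means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import precision_recall_curve, roc_curve

from .postproc import PostprocParams, segment

__all__ = [
    "ConfusionCounts",
    "ObjectMatching",
    "MetricReport",
    "pixel_confusion",
    "pixel_metrics",
    "dice_pixel",
    "aji",
    "match_objects",
    "object_pr",
    "roc_pr_curves",
    "threshold_sweep",
    "evaluate_patches",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


@dataclass
class ObjectMatching:
    """One-to-one instance matches: (gt id, pred id, IoU) triples plus the
    leftovers on both sides."""

    pairs: list[tuple[int, int, float]]
    unmatched_gt: list[int]
    unmatched_pred: list[int]


@dataclass
class MetricReport:
    """Aggregate + per-patch evaluation results; absent metrics are None."""

    acc: float | None = None
    sen: float | None = None
    spe: float | None = None
    dice: float | None = None
    aji: float | None = None
    precision: float | None = None
    recall: float | None = None
    auc_roc: float | None = None
    auc_pr: float | None = None
    per_patch: pd.DataFrame | None = None
    n_undefined: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("acc", "sen", "spe", "dice", "aji", "precision", "recall",
                 "auc_roc", "auc_pr")}


def pixel_confusion(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Per-pixel confusion counts; the four counts partition all pixels."""
    pred = np.asarray(pred, dtype=bool)
    gt = np.asarray(gt, dtype=bool)
    if pred.shape != gt.shape:
        raise ValueError("pred and gt shapes differ")
    tp = int(np.count_nonzero(pred & gt))
    fp = int(np.count_nonzero(pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    tn = pred.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def pixel_metrics(c: ConfusionCounts):
    """(accuracy, sensitivity, specificity); undefined ratios come back as
    ``None`` (e.g. sensitivity when the ground truth has no positives)."""
    if c.total == 0:
        raise ValueError("empty confusion matrix")
    acc = (c.tp + c.tn) / c.total
    sen = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    spe = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else None
    return acc, sen, spe


def dice_pixel(pred: np.ndarray, gt: np.ndarray) -> float | None:
    """Dice = 2 TP / (2 TP + FP + FN); ``None`` when both masks are empty."""
    c = pixel_confusion(pred, gt)
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return None
    return 2 * c.tp / denom


def _overlap_table(gt: np.ndarray, pred: np.ndarray):
    """Sparse intersection counts between every (gt, pred) instance pair."""
    gt = np.asarray(gt).ravel()
    pred = np.asarray(pred).ravel()
    both = (gt > 0) & (pred > 0)
    pairs, counts = np.unique(
        np.stack([gt[both], pred[both]]), axis=1, return_counts=True)
    table: dict[tuple[int, int], int] = {}
    for (g, p), c in zip(pairs.T, counts):
        table[(int(g), int(p))] = int(c)
    return table


def _areas(labels: np.ndarray) -> dict[int, int]:
    ids, counts = np.unique(np.asarray(labels)[np.asarray(labels) > 0],
                            return_counts=True)
    return {int(i): int(c) for i, c in zip(ids, counts)}


def aji(gt: np.ndarray, pred: np.ndarray) -> float:
    """Aggregated Jaccard index between two instance label maps.

    Each ground-truth instance selects the prediction maximising its Jaccard
    index; predictions are consumed at most once, claims resolved greedily
    in descending best-Jaccard order (ties by lower prediction id).  Matched
    intersections sum in the numerator; matched unions, unmatched
    ground-truth areas and never-used prediction areas sum in the
    denominator.  1 for identical maps (up to relabelling), 0 when nothing
    overlaps.
    """
    gt = np.asarray(gt)
    pred = np.asarray(pred)
    if gt.shape != pred.shape:
        raise ValueError("gt and pred shapes differ")
    gt_areas = _areas(gt)
    pred_areas = _areas(pred)
    if not gt_areas and not pred_areas:
        return 1.0  # vacuously identical
    if not gt_areas:
        return 0.0
    overlaps = _overlap_table(gt, pred)
    # candidate (jaccard, gt, pred) per gt instance
    best: list[tuple[float, int, int]] = []
    cand: dict[int, list[tuple[float, int]]] = {g: [] for g in gt_areas}
    for (g, p), inter in overlaps.items():
        union = gt_areas[g] + pred_areas[p] - inter
        cand[g].append((inter / union, p))
    for g, lst in cand.items():
        lst.sort(key=lambda t: (-t[0], t[1]))
    order = sorted(gt_areas, key=lambda g: (-(cand[g][0][0] if cand[g] else 0.0), g))
    used: set[int] = set()
    numerator = 0
    denominator = 0
    for g in order:
        chosen = None
        for j, p in cand[g]:
            if p not in used:
                chosen = p
                break
        if chosen is None:
            denominator += gt_areas[g]  # union with the empty set
            continue
        inter = overlaps[(g, chosen)]
        union = gt_areas[g] + pred_areas[chosen] - inter
        numerator += inter
        denominator += union
        used.add(chosen)
    for p, area in pred_areas.items():
        if p not in used:
            denominator += area
    if denominator == 0:
        return 1.0
    return numerator / denominator


def match_objects(gt: np.ndarray, pred: np.ndarray,
                  iou_threshold: float = 0.5) -> ObjectMatching:
    """Greedy one-to-one matching of instances by descending pairwise IoU;
    a pair counts only when IoU >= ``iou_threshold``."""
    if not (0.0 < iou_threshold <= 1.0):
        raise ValueError("iou_threshold must lie in (0, 1]")
    gt = np.asarray(gt)
    pred = np.asarray(pred)
    if gt.shape != pred.shape:
        raise ValueError("gt and pred shapes differ")
    gt_areas = _areas(gt)
    pred_areas = _areas(pred)
    overlaps = _overlap_table(gt, pred)
    candidates = []
    for (g, p), inter in overlaps.items():
        iou = inter / (gt_areas[g] + pred_areas[p] - inter)
        if iou >= iou_threshold:
            candidates.append((iou, g, p))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_g: set[int] = set()
    used_p: set[int] = set()
    pairs = []
    for iou, g, p in candidates:
        if g in used_g or p in used_p:
            continue
        pairs.append((g, p, iou))
        used_g.add(g)
        used_p.add(p)
    return ObjectMatching(
        pairs=pairs,
        unmatched_gt=sorted(set(gt_areas) - used_g),
        unmatched_pred=sorted(set(pred_areas) - used_p),
    )


def object_pr(m: ObjectMatching):
    """(precision, recall) at object level.

    precision = matches / (matches + unmatched predictions); ``None`` when
    there are no predictions at all.  recall = matches / (matches +
    unmatched ground truth); ``None`` without ground-truth objects.
    """
    tp = len(m.pairs)
    n_pred = tp + len(m.unmatched_pred)
    n_gt = tp + len(m.unmatched_gt)
    precision = tp / n_pred if n_pred > 0 else None
    recall = tp / n_gt if n_gt > 0 else None
    return precision, recall


def roc_pr_curves(prob_maps: Sequence[np.ndarray],
                  gt_binaries: Sequence[np.ndarray]):
    """Pixel-pooled ROC and precision-recall curves.

    Returns ``(roc_df, auc_roc, pr_df, auc_pr)`` with curve points as
    DataFrames; AUCs by trapezoidal integration.
    """
    if len(prob_maps) != len(gt_binaries):
        raise ValueError("need one ground truth per probability map")
    scores = np.concatenate([np.asarray(p).ravel() for p in prob_maps])
    labels = np.concatenate(
        [np.asarray(g).astype(bool).ravel() for g in gt_binaries])
    if labels.all() or not labels.any():
        raise ValueError("pooled ground truth needs both classes")
    fpr, tpr, roc_thr = roc_curve(labels, scores)
    auc_roc = float(_trapezoid_auc(fpr, tpr))
    prec, rec, pr_thr = precision_recall_curve(labels, scores)
    # PR points come back in decreasing-recall order; integrate over recall
    auc_pr = float(_trapezoid_auc(rec[::-1], prec[::-1]))
    roc_df = pd.DataFrame({"fpr": fpr, "tpr": tpr,
                           "threshold": roc_thr})
    pr_df = pd.DataFrame({"recall": rec, "precision": prec})
    return roc_df, auc_roc, pr_df, auc_pr


def threshold_sweep(
    prob_maps: Sequence[np.ndarray],
    gt_instances: Sequence[np.ndarray],
    thresholds: Sequence[float] = (0.30, 0.35, 0.40, 0.45, 0.50),
    h: float = 6.0,
    iou_threshold: float = 0.5,
    min_area: int = 0,
) -> pd.DataFrame:
    """Object-level precision/recall per probability threshold.

    For each threshold the full post-processing chain runs (binarize ->
    watershed separation -> small-object removal), instances are matched
    one-to-one against ground truth, and object counts pool over patches.
    Returns a DataFrame ``threshold, precision, recall`` (one row per
    threshold, ascending).
    """
    thresholds = list(thresholds)
    if sorted(thresholds) != thresholds:
        raise ValueError("thresholds must be sorted ascending")
    rows = []
    for thr in thresholds:
        params = PostprocParams(prob_threshold=thr, h=h, min_area=min_area)
        tp = n_pred = n_gt = 0
        for prob, gt in zip(prob_maps, gt_instances):
            pred = segment(np.asarray(prob), params)
            m = match_objects(np.asarray(gt), pred, iou_threshold)
            tp += len(m.pairs)
            n_pred += len(m.pairs) + len(m.unmatched_pred)
            n_gt += len(m.pairs) + len(m.unmatched_gt)
        rows.append({
            "threshold": thr,
            "precision": tp / n_pred if n_pred else None,
            "recall": tp / n_gt if n_gt else None,
        })
    return pd.DataFrame(rows)


def evaluate_patches(
    prob_maps: Sequence[np.ndarray],
    gt_binaries: Sequence[np.ndarray],
    gt_instances: Sequence[np.ndarray] | None = None,
    params: PostprocParams | None = None,
    iou_threshold: float = 0.5,
    mode: str = "pooled",
) -> MetricReport:
    """One-stop evaluation of a set of predictions.

    ``mode='pooled'`` aggregates pixel counts over all patches before
    computing ratios; ``mode='patch_mean'`` averages per-patch metrics
    (undefined patches excluded).  Object metrics require ``gt_instances``.
    """
    if mode not in ("pooled", "patch_mean"):
        raise ValueError("mode must be 'pooled' or 'patch_mean'")
    params = params or PostprocParams()
    report = MetricReport()
    per_patch = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    pred_instances = []
    for i, (prob, gtb) in enumerate(zip(prob_maps, gt_binaries)):
        pred_bin = np.asarray(prob) >= params.prob_threshold
        c = pixel_confusion(pred_bin, gtb)
        pooled = pooled + c
        acc, sen, spe = pixel_metrics(c)
        row = {"patch": i, "acc": acc, "sen": sen, "spe": spe,
               "dice": dice_pixel(pred_bin, gtb)}
        if gt_instances is not None:
            pred_inst = segment(np.asarray(prob), params)
            pred_instances.append(pred_inst)
            row["aji"] = aji(np.asarray(gt_instances[i]), pred_inst)
            m = match_objects(np.asarray(gt_instances[i]), pred_inst,
                              iou_threshold)
            row["obj_tp"] = len(m.pairs)
            row["obj_pred"] = len(m.pairs) + len(m.unmatched_pred)
            row["obj_gt"] = len(m.pairs) + len(m.unmatched_gt)
        per_patch.append(row)
    df = pd.DataFrame(per_patch)
    report.per_patch = df

    if mode == "pooled":
        report.acc, report.sen, report.spe = pixel_metrics(pooled)
        denom = 2 * pooled.tp + pooled.fp + pooled.fn
        report.dice = 2 * pooled.tp / denom if denom else None
    else:
        for key in ("acc", "sen", "spe", "dice"):
            vals = df[key].dropna()
            setattr(report, key, float(vals.mean()) if len(vals) else None)
            report.n_undefined[key] = int(df[key].isna().sum())
    if gt_instances is not None:
        vals = df["aji"].dropna()
        report.aji = float(vals.mean()) if len(vals) else None
        tp = int(df["obj_tp"].sum())
        n_pred = int(df["obj_pred"].sum())
        n_gt = int(df["obj_gt"].sum())
        report.precision = tp / n_pred if n_pred else None
        report.recall = tp / n_gt if n_gt else None
    try:
        _, report.auc_roc, _, report.auc_pr = roc_pr_curves(prob_maps,
                                                            gt_binaries)
    except ValueError:
        pass  # single-class pool: curves undefined
    return report
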