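"""Mask-matched average precision (the competition-style metric).

Predicted cells are greedily matched to ground-truth cells at mask IoU
strictly above 0.6 in descending confidence order; each matched prediction
is a true positive for every class its ground-truth cell carries. Per-class
average precision is the all-point (non-interpolated) area under the
precision-recall curve over detections ranked by confidence, and the final
score is the unweighted mean over classes:

    ``mAP = (1 / C) * sum_i Prec_i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

IOU_THRESHOLD = 0.6


@dataclass
class MatchResult:
    pairs: list[tuple[int, int, float]]      # (pred index, gt index, IoU)
    unmatched_predictions: list[int]
    unmatched_ground_truths: list[int]


@dataclass
class APResult:
    """Per-class AP (NaN for classes with no ground-truth positives, which
    are excluded from the mean) and their unweighted mean."""

    per_class_ap: np.ndarray
    map: float

    @classmethod
    def from_per_class(cls, per_class_ap: np.ndarray) -> "APResult":
        per_class_ap = np.asarray(per_class_ap, dtype=float)
        valid = per_class_ap[~np.isnan(per_class_ap)]
        return cls(per_class_ap=per_class_ap,
                   map=mean_ap(valid) if valid.size else 0.0)


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two binary masks; 0 for an empty union."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def match_cells(pred_masks: list[np.ndarray], confidences: np.ndarray,
                gt_masks: list[np.ndarray],
                iou_thresh: float = IOU_THRESHOLD) -> MatchResult:
    """Greedy matching in descending confidence.

    Each prediction claims the still-unmatched ground truth of highest IoU
    strictly above the threshold; a ground truth is matched at most once.
    """
    confidences = np.asarray(confidences, dtype=float)
    order = np.argsort(-confidences, kind="stable")
    taken = np.zeros(len(gt_masks), dtype=bool)
    pairs: list[tuple[int, int, float]] = []
    unmatched_pred: list[int] = []
    for p in order:
        best_iou, best_g = iou_thresh, -1
        for g in range(len(gt_masks)):
            if taken[g]:
                continue
            iou = mask_iou(pred_masks[p], gt_masks[g])
            if iou > best_iou:
                best_iou, best_g = iou, g
        if best_g >= 0:
            taken[best_g] = True
            pairs.append((int(p), best_g, best_iou))
        else:
            unmatched_pred.append(int(p))
    unmatched_gt = [g for g in range(len(gt_masks)) if not taken[g]]
    return MatchResult(pairs=pairs, unmatched_predictions=sorted(unmatched_pred),
                       unmatched_ground_truths=unmatched_gt)


def average_precision(detections: list[tuple[float, bool]], n_positives: int) -> float:
    """All-point area under the precision-recall curve.

    ``detections`` are ``(confidence, is_true_positive)`` pairs; they are
    ranked by descending confidence and precision is accumulated at every
    true-positive rank. Zero when there are no positives to recover.
    """
    if n_positives < 0:
        raise ValueError("n_positives must be nonnegative")
    if n_positives == 0:
        return 0.0
    if not detections:
        return 0.0
    conf = np.asarray([c for c, _ in detections], dtype=float)
    tp = np.asarray([bool(t) for _, t in detections])
    order = np.argsort(-conf, kind="stable")
    tp = tp[order]
    cum_tp = np.cumsum(tp)
    ranks = np.arange(1, len(tp) + 1)
    precision_at_tp = cum_tp[tp] / ranks[tp]
    return float(precision_at_tp.sum() / n_positives)


def mean_ap(per_class_ap: np.ndarray) -> float:
    """Unweighted mean over classes."""
    per_class_ap = np.asarray(per_class_ap, dtype=float)
    if per_class_ap.size == 0:
        raise ValueError("no classes to average")
    return float(per_class_ap.mean())


# ---------------------------------------------------------------------------
# higher-level scoring

def detection_lists(match: MatchResult, pred_probs: np.ndarray,
                    gt_labels: np.ndarray) -> tuple[list[list[tuple[float, bool]]], np.ndarray]:
    """Per-class detections from one image's matching result.

    Every prediction emits one detection per class with its class
    probability as confidence; it is a true positive when matched to a
    ground-truth cell carrying that class.
    """
    n_classes = pred_probs.shape[1]
    matched_gt = {p: g for p, g, _ in match.pairs}
    dets: list[list[tuple[float, bool]]] = [[] for _ in range(n_classes)]
    for p in range(len(pred_probs)):
        g = matched_gt.get(p)
        for c in range(n_classes):
            is_tp = g is not None and gt_labels[g, c] > 0
            dets[c].append((float(pred_probs[p, c]), bool(is_tp)))
    n_pos = (np.asarray(gt_labels) > 0).sum(axis=0)
    return dets, n_pos


def score_matched(probs: np.ndarray, gt_labels: np.ndarray) -> APResult:
    """mAP when predicted cells coincide with ground-truth cells.

    The common benchmark case: segmentation is taken from ground truth, so
    every cell matches itself with IoU 1 and the metric reduces to
    per-class detection AP over cells.
    """
    probs = np.asarray(probs, dtype=float)
    gt = np.asarray(gt_labels)
    if probs.shape != gt.shape:
        raise ValueError("probability and label shapes differ")
    n_classes = probs.shape[1]
    aps = np.zeros(n_classes)
    for c in range(n_classes):
        n_pos = int((gt[:, c] > 0).sum())
        if n_pos == 0:
            aps[c] = np.nan  # class absent from this manifest: not scorable
            continue
        dets = [(float(p), bool(t > 0)) for p, t in zip(probs[:, c], gt[:, c])]
        aps[c] = average_precision(dets, n_pos)
    return APResult.from_per_class(aps)


def score_images(per_image: list[dict], n_classes: int,
                 iou_thresh: float = IOU_THRESHOLD) -> APResult:
    """Full mask-matched mAP over a list of images.

    Each entry carries ``pred_masks``, ``pred_probs``, ``gt_masks`` and
    ``gt_labels``; detections are pooled over images per class.
    """
    pooled: list[list[tuple[float, bool]]] = [[] for _ in range(n_classes)]
    n_pos = np.zeros(n_classes, dtype=int)
    for entry in per_image:
        conf = np.asarray(entry["pred_probs"]).max(axis=1)
        match = match_cells(entry["pred_masks"], conf, entry["gt_masks"], iou_thresh)
        dets, pos = detection_lists(match, np.asarray(entry["pred_probs"]),
                                    np.asarray(entry["gt_labels"]))
        for c in range(n_classes):
            pooled[c].extend(dets[c])
        n_pos += pos
    aps = np.array([average_precision(pooled[c], int(n_pos[c]))
                    if n_pos[c] > 0 else np.nan
                    for c in range(n_classes)])
    return APResult.from_per_class(aps)
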