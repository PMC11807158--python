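"""Evaluation: Dice score, box IoU, precision/recall, average precision
(AP50 / AP75 / mAP), per-layer Dice reports and paired method comparison.

Detection metrics follow the COCO protocol choices: detections are matched
to ground truth greedily in descending confidence with one-to-one matching
per image; AP is the 101-point interpolated area under the precision-recall
curve; mAP averages AP over the IoU grid 0.50:0.05:0.95.  AP values are
reported on the 0-100 scale.

Segmentation reports give per-layer Dice mean +/- sd over images and an
overall score computed by averaging layers within each image first, then
averaging over images (the aggregation is stated in the report header).
For diseased scans, sublayer Dice is evaluated only outside the
ground-truth box, where sublayer ground truth is defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .types import SUBLAYER_IDS, SUBLAYER_NAMES, BoxAnnotation, Detection

COCO_IOU_GRID = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))
UNDEFINED = float("nan")  # sentinel for Dice of a class absent in both masks


# ---------------------------------------------------------------------------
# Pixel overlap
# ---------------------------------------------------------------------------

def dice_score(pred: np.ndarray, gt: np.ndarray, class_id: int,
               region: Optional[np.ndarray] = None) -> float:
    """Dice coefficient 2|P∩G| / (|P|+|G|) for one class.

    ``region`` optionally restricts evaluation (True/1 = evaluate), used to
    exclude box interiors in sublayer mode.  Returns NaN when the class is
    absent from both masks (undefined; excluded from averages).
    """

    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError("pred/gt shapes differ")
    p = pred == class_id
    g = gt == class_id
    if region is not None:
        r = np.asarray(region).astype(bool)
        p = p & r
        g = g & r
    denom = p.sum() + g.sum()
    if denom == 0:
        return UNDEFINED
    return float(2.0 * np.logical_and(p, g).sum() / denom)


def box_iou(a: BoxAnnotation, b: BoxAnnotation) -> float:
    """Intersection-over-union of two half-open boxes."""

    if a.area == 0 or b.area == 0:
        warnings.warn("zero-area box in IoU")
        return 0.0
    ix = max(0, min(a.x_end, b.x_end) - max(a.x_start, b.x_start))
    iy = max(0, min(a.y_end, b.y_end) - max(a.y_start, b.y_start))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union else 0.0


# ---------------------------------------------------------------------------
# Detection matching and AP
# ---------------------------------------------------------------------------

GroundTruths = Mapping[object, Sequence[BoxAnnotation]]


def _greedy_match(detections: Sequence[Detection], gts: GroundTruths,
                  iou_threshold: float) -> Tuple[List[bool], int]:
    """Greedy one-to-one matching in descending confidence.

    Returns (per-detection TP flags in confidence order, total GT count).
    """

    order = sorted(range(len(detections)),
                   key=lambda i: (-detections[i].score, str(detections[i].image_id), i))
    matched: Dict[object, set] = {}
    flags: List[bool] = []
    for i in order:
        det = detections[i]
        candidates = gts.get(det.image_id, [])
        used = matched.setdefault(det.image_id, set())
        best_iou, best_j = 0.0, -1
        for j, gt in enumerate(candidates):
            if j in used:
                continue
            iou = box_iou(det.box, gt)
            if iou > best_iou:
                best_iou, best_j = iou, j
        if best_j >= 0 and best_iou >= iou_threshold:
            used.add(best_j)
            flags.append(True)
        else:
            flags.append(False)
    n_gt = sum(len(v) for v in gts.values())
    return flags, n_gt


@dataclass(frozen=True)
class PRResult:
    precision: float
    recall: float
    tp: int
    fp: int
    fn: int


def precision_recall(detections: Sequence[Detection], gts: GroundTruths,
                     iou_threshold: float,
                     confidence_threshold: float = 0.5) -> PRResult:
    """Precision = TP/(TP+FP), Recall = TP/(TP+FN) at one operating point.

    Detections below ``confidence_threshold`` are discarded; matching is
    greedy one-to-one at ``iou_threshold``.  With neither detections nor
    ground truth both metrics are vacuously 1.
    """

    kept = [d for d in detections if d.score >= confidence_threshold]
    flags, n_gt = _greedy_match(kept, gts, iou_threshold)
    tp = sum(flags)
    fp = len(flags) - tp
    fn = n_gt - tp
    precision = tp / (tp + fp) if (tp + fp) else 1.0
    recall = tp / n_gt if n_gt else 1.0
    return PRResult(precision, recall, tp, fp, fn)


def average_precision(detections: Sequence[Detection], gts: GroundTruths,
                      iou_threshold: float,
                      return_curve: bool = False):
    """101-point interpolated AP (0-100 scale) at one IoU threshold.

    Raises ``ValueError`` when the ground-truth set is empty (AP
    undefined).
    """

    flags, n_gt = _greedy_match(detections, gts, iou_threshold)
    if n_gt == 0:
        raise ValueError("AP undefined: no ground-truth boxes")
    tp = np.cumsum(flags) if flags else np.array([])
    fp = np.cumsum([not f for f in flags]) if flags else np.array([])
    recall = tp / n_gt if len(tp) else np.array([])
    precision = tp / np.maximum(tp + fp, 1) if len(tp) else np.array([])
    grid = np.linspace(0.0, 1.0, 101)
    interp = np.zeros_like(grid)
    for i, r in enumerate(grid):
        sel = recall >= r if len(recall) else np.array([], dtype=bool)
        interp[i] = precision[sel].max() if sel.any() else 0.0
    ap = float(interp.mean() * 100.0)
    if return_curve:
        return ap, pd.DataFrame({"recall": grid, "precision": interp})
    return ap


@dataclass
class APResult:
    """AP per IoU threshold on the 0-100 scale, plus the summary trio."""

    per_threshold: Dict[float, float]
    ap50: float
    ap75: float
    map: float
    pr_curve_50: Optional[pd.DataFrame] = None


def ap_summary(detections: Sequence[Detection], gts: GroundTruths,
               iou_grid: Sequence[float] = COCO_IOU_GRID) -> APResult:
    """AP50, AP75 and mAP over the IoU threshold grid."""

    per = {float(t): average_precision(detections, gts, float(t))
           for t in iou_grid}
    _, curve = average_precision(detections, gts, 0.5, return_curve=True)
    return APResult(per_threshold=per,
                    ap50=per.get(0.5, UNDEFINED),
                    ap75=per.get(0.75, UNDEFINED),
                    map=float(np.mean(list(per.values()))),
                    pr_curve_50=curve)


# ---------------------------------------------------------------------------
# Segmentation reports
# ---------------------------------------------------------------------------

@dataclass
class DiceReport:
    """Per-image per-layer Dice plus summary mean +/- sd rows."""

    per_image: pd.DataFrame      # one row per image, one column per layer
    summary: pd.DataFrame        # rows: layers + Overall; cols: mean, sd
    aggregation: str = ("overall = mean over layers within each image, "
                        "then mean over images; undefined classes excluded")

    def overall_mean(self) -> float:
        return float(self.summary.loc["Overall", "mean"])


def evaluate_segmentation(predictions: Sequence[np.ndarray],
                          ground_truths: Sequence[np.ndarray],
                          mode: str = "sublayer",
                          boxes: Optional[Sequence[Optional[BoxAnnotation]]] = None
                          ) -> DiceReport:
    """Per-layer Dice over a test set.

    ``mode="sublayer"`` scores the five sublayers, restricted to outside
    each image's ground-truth box (sublayer truth is undefined inside);
    ``mode="total"`` scores the single total-retina class on the full
    image.  Summary sd uses the sample definition (ddof=1).
    """

    if len(predictions) == 0:
        raise ValueError("empty test set")
    if len(predictions) != len(ground_truths):
        raise ValueError("predictions/ground truths length mismatch")
    if mode == "sublayer":
        classes = list(SUBLAYER_IDS)
        names = [SUBLAYER_NAMES[c] for c in classes]
    elif mode == "total":
        classes = [1]
        names = ["Total retina"]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    rows = []
    for i, (pred, gt) in enumerate(zip(predictions, ground_truths)):
        region = None
        if mode == "sublayer" and boxes is not None and boxes[i] is not None:
            from .losses import box_to_mask
            region = box_to_mask(boxes[i], gt.shape)
        rows.append({name: dice_score(pred, gt, c, region)
                     for name, c in zip(names, classes)})
    per_image = pd.DataFrame(rows)
    per_image["Overall"] = per_image[names].mean(axis=1, skipna=True)

    summary = pd.DataFrame({
        "mean": per_image.mean(axis=0, skipna=True),
        "sd": per_image.std(axis=0, ddof=1, skipna=True),
    })
    return DiceReport(per_image=per_image, summary=summary)


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    p: float
    dof: int
    mean_difference: float
    degenerate: bool = False  # zero-variance differences


def compare_methods(dice_a: Sequence[float], dice_b: Sequence[float]
                    ) -> PairedTestResult:
    """Two-sided paired t-test on per-image overall Dice of two methods.

    Zero-variance differences are reported explicitly as degenerate:
    identical vectors give t=0, p=1; a constant nonzero difference gives
    t=+/-inf, p=0.
    """

    a = np.asarray(dice_a, dtype=float)
    b = np.asarray(dice_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two paired 1-D vectors of equal length >= 2")
    d = a - b
    n = d.size
    sd = d.std(ddof=1)
    mean = float(d.mean())
    if sd == 0.0:
        if mean == 0.0:
            return PairedTestResult(0.0, 1.0, n - 1, 0.0, degenerate=True)
        t = float(np.sign(mean)) * float("inf")
        return PairedTestResult(t, 0.0, n - 1, mean, degenerate=True)
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return PairedTestResult(float(t), float(p), n - 1, mean)
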