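"""Iterative annotation loop and the composed three-stage pipeline.

The iterative loop emulates the annotation-budget workflow: start from a
small annotated training set, train, evaluate on a *fixed* validation set,
then move 200 randomly chosen B-scans from the unannotated pool into the
training set (the phantom ground truth stands in for the human annotator)
and repeat.  Validation and test sets never change across loops, and test
patients never enter any training manifest.

The pipeline composes the three stages per test image: box detection ->
total-retina segmentation -> pathology-aware sublayer segmentation ->
composed label map, and emits the full evaluation report (detection AP,
total-retina Dice, per-sublayer Dice outside ground-truth boxes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as paio
from .detect import DetectorContract, top_detection
from .metrics import (APResult, DiceReport, ap_summary,
                      evaluate_segmentation)
from .segment import MLPSegmenter, aggregate_sublayers_to_total, \
    compose_prediction
from .types import BoxAnnotation, Detection, LabelMask

# train_fn(train_manifest, val_manifest, loop, seed) -> (model, val_metric)
TrainFn = Callable[[pd.DataFrame, pd.DataFrame, int, int],
                   Tuple[object, float]]


@dataclass
class LoopState:
    """Bookkeeping for one iteration of the annotation loop."""

    loop: int
    n_annotated: int
    n_pool: int
    val_metric: float
    val_manifest_hash: str
    stopped: bool = False


def run_iterative(train_fn: TrainFn,
                  initial_train: pd.DataFrame,
                  pool: pd.DataFrame,
                  validation: pd.DataFrame,
                  loops: int,
                  per_loop: int = 200,
                  seed: int = 0,
                  plateau_tol: Optional[float] = None,
                  plateau_loops: int = 2
                  ) -> Tuple[List[LoopState], object, pd.DataFrame]:
    """Run the iterative learning loop.

    Each loop trains on the current annotated set, records the validation
    metric, then transfers ``per_loop`` random pool rows (or the pool
    remainder) into the annotated set.  Returns (history, final model,
    final annotated manifest).  With ``plateau_tol`` set, the loop stops
    early once the validation metric improves by less than ``plateau_tol``
    (absolute) for ``plateau_loops`` consecutive loops.
    """

    rng = np.random.default_rng(seed)
    annotated = initial_train.reset_index(drop=True)
    pool = pool.reset_index(drop=True)
    val_hash = paio.manifest_hash(validation)
    history: List[LoopState] = []
    model: object = None
    best_metric = -np.inf
    stale = 0

    for loop in range(loops):
        model, metric = train_fn(annotated, validation, loop, seed)
        state = LoopState(loop=loop, n_annotated=len(annotated),
                          n_pool=len(pool), val_metric=float(metric),
                          val_manifest_hash=val_hash)
        history.append(state)

        if plateau_tol is not None:
            if metric <= best_metric + plateau_tol:
                stale += 1
            else:
                stale = 0
            best_metric = max(best_metric, metric)
            if stale >= plateau_loops:
                state.stopped = True
                break

        take = min(per_loop, len(pool))
        if take == 0:
            warnings.warn("unannotated pool exhausted: stopping early")
            state.stopped = True
            break
        idx = rng.choice(len(pool), size=take, replace=False)
        moved = pool.iloc[np.sort(idx)]
        pool = pool.drop(pool.index[np.sort(idx)]).reset_index(drop=True)
        annotated = pd.concat([annotated, moved], ignore_index=True)

    return history, model, annotated


@dataclass
class PipelineReport:
    """Full evaluation bundle for a test set."""

    detection: Optional[APResult]
    total: DiceReport
    sublayer: DiceReport
    composed: List[LabelMask] = field(repr=False, default_factory=list)


def run_pipeline(images: Sequence[np.ndarray],
                 gt_total: Sequence[np.ndarray],
                 gt_sublayer: Sequence[np.ndarray],
                 gt_boxes: Sequence[Optional[BoxAnnotation]],
                 detector: DetectorContract,
                 total_model: MLPSegmenter,
                 sublayer_model: MLPSegmenter) -> PipelineReport:
    """Detect -> segment total -> segment sublayers -> compose -> evaluate.

    Detection AP is computed when the test set holds at least one
    ground-truth box; total-retina Dice uses the full image; sublayer Dice
    is restricted to outside the ground-truth boxes, where sublayer truth
    exists.
    """

    if any(m is None for m in (detector, total_model, sublayer_model)):
        raise ValueError("all three stage models must be provided")

    detections: List[Detection] = []
    composed: List[LabelMask] = []
    total_preds: List[np.ndarray] = []
    sub_preds: List[np.ndarray] = []
    for i, img in enumerate(images):
        dets = detector.predict(img)
        for d in dets:
            detections.append(Detection(box=d.box, score=d.score, image_id=i))
        top = top_detection(dets)
        composed.append(compose_prediction(img, top, total_model,
                                           sublayer_model))
        total_preds.append(total_model.predict_labels(img))
        sub_preds.append(sublayer_model.predict_labels(img))

    gts: Dict[object, List[BoxAnnotation]] = {
        i: [b] for i, b in enumerate(gt_boxes) if b is not None}
    detection_report = ap_summary(detections, gts) if gts else None

    total_report = evaluate_segmentation(total_preds, gt_total, mode="total")
    sublayer_report = evaluate_segmentation(sub_preds, gt_sublayer,
                                            mode="sublayer", boxes=gt_boxes)
    return PipelineReport(detection=detection_report, total=total_report,
                          sublayer=sublayer_report, composed=composed)


# ---------------------------------------------------------------------------
# Manifest-backed data loading for CLI runs
# ---------------------------------------------------------------------------

def load_scans(data_dir: Path, manifest: pd.DataFrame
               ) -> Tuple[List[np.ndarray], List[np.ndarray],
                          List[np.ndarray], List[Optional[BoxAnnotation]]]:
    """Load (images, sublayer labels, total labels, boxes) for a manifest."""

    data_dir = Path(data_dir)
    boxes_file = data_dir / "boxes.json"
    all_boxes = paio.load_coco_boxes(boxes_file) if boxes_file.exists() else {}
    images, subs, totals, boxes = [], [], [], []
    for row in manifest.itertuples():
        images.append(paio.load_image(data_dir / row.image_path))
        subs.append(paio.load_mask(data_dir / row.sublayer_mask_path,
                                   "sublayer").labels)
        totals.append(paio.load_mask(data_dir / row.total_mask_path,
                                     "total").labels)
        boxes.append(all_boxes.get(getattr(row, "scan_id", None)))
    return images, subs, totals, boxes
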