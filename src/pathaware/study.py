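"""The desk-scale reference study: frozen cohort conditions and the
standard-vs-pathology-aware comparison experiment.

This module pins the configuration used by the package's reproducibility
scripts: a 259-patient multi-site bookkeeping cohort (manifest-level only),
and a reduced-scale imaging study on 320x160 phantoms — 50 healthy plus 50
diseased training B-scans, 10 training epochs — on which the pathology-
aware sublayer model is compared against a standard model trained on
healthy scans only, and the rule-based lesion detector is scored with
AP50/AP75/mAP.  All randomness flows from a single seed.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import metrics, segment
from .detect import RuleBasedDetector, top_detection
from .phantom import CohortSpec, PhantomSpec, plan_cohort, realize_scan
from .types import BoxAnnotation, Detection, LabelMask

# Multi-site enrollment (259 patients over 9 sites) used for bookkeeping:
# under the per-site 8:1:1 floor-with-min-1 rule this yields 203 training
# and 28 validation / 28 test patients.
BOOKKEEPING_SITES: Dict[str, int] = {
    "site1": 90, "site2": 80, "site3": 40, "site4": 20, "site5": 10,
    "site6": 10, "site7": 3, "site8": 3, "site9": 3,
}

REDUCED_WIDTH = 320
REDUCED_HEIGHT = 160
N_TRAIN_PER_ARM = 50
N_VAL_PER_ARM = 5
N_TEST_HEALTHY = 20
N_TEST_DISEASED = 20
EPOCHS = 10


def reduced_phantom() -> PhantomSpec:
    """The reduced-resolution phantom used by the desk-scale experiments."""

    return PhantomSpec(width=REDUCED_WIDTH, height=REDUCED_HEIGHT)


ScanSet = Tuple[List[np.ndarray], List[np.ndarray], List[np.ndarray],
                List[Optional[BoxAnnotation]]]


def build_scan_set(diseased: bool, n: int, seed: int,
                   phantom: Optional[PhantomSpec] = None) -> ScanSet:
    """Render ``n`` phantom B-scans drawn from a small cohort.

    Returns (images, sublayer labels, total labels, boxes).
    """

    spec = CohortSpec(sites={"s": max(1, n // 10)}, visits=5,
                      eyes=("OD", "OS"), slices_per_volume=1,
                      diseased=diseased,
                      phantom=phantom or reduced_phantom(), seed=seed)
    manifest = plan_cohort(spec)
    manifest = manifest.sample(n=n, random_state=seed).reset_index(drop=True)
    scans = [realize_scan(r, spec) for r in manifest.to_dict("records")]
    return ([s[0] for s in scans], [s[1].labels for s in scans],
            [s[2].labels for s in scans], [s[3] for s in scans])


def run_directional_experiment(seed: int = 7) -> Dict[str, object]:
    """Standard-on-healthy vs pathology-aware-on-mixed sublayer training.

    Mirrors the published comparison as an ordering: the standard model is
    trained exclusively on healthy scans (diseased sublayer annotation
    does not exist inside lesions), while the pathology-aware model trains
    on an equal share of healthy and diseased scans with box-derived
    exclusion masks.  Both are evaluated on held-out healthy and diseased
    test sets; diseased sublayer Dice is computed outside the ground-truth
    boxes.  Returns the two fitted models, the test sets and the four
    overall Dice scores plus a paired t-test on the diseased test set.
    """

    s = int(seed)
    hi, hs, ht, hb = build_scan_set(False, N_TRAIN_PER_ARM, s * 10 + 1)
    di, ds, dt, db = build_scan_set(True, N_TRAIN_PER_ARM, s * 10 + 2)
    hvi, hvs, hvt, hvb = build_scan_set(False, N_VAL_PER_ARM, s * 10 + 3)
    dvi, dvs, dvt, dvb = build_scan_set(True, N_VAL_PER_ARM, s * 10 + 4)
    thi, ths, tht, thb = build_scan_set(False, N_TEST_HEALTHY, s * 10 + 5)
    tdi, tds, tdt, tdb = build_scan_set(True, N_TEST_DISEASED, s * 10 + 6)

    cfg_std = segment.TrainConfig(epochs=EPOCHS, seed=s,
                                  loss_mode="standard")
    cfg_pa = segment.TrainConfig(epochs=EPOCHS, seed=s,
                                 loss_mode="pathology_aware")

    standard, _ = segment.train_sublayers(hi, hs, hvi, hvs, None, None,
                                          cfg_std)
    pa_model, _ = segment.train_sublayers(hi + di, hs + ds, hvi + dvi,
                                          hvs + dvs,
                                          list(hb) + list(db),
                                          list(hvb) + list(dvb), cfg_pa)

    def overall(model, images, subs, boxes) -> metrics.DiceReport:
        preds = [model.predict_labels(im) for im in images]
        return metrics.evaluate_segmentation(preds, subs, "sublayer", boxes)

    rep = {
        "standard_healthy": overall(standard, thi, ths, thb),
        "standard_diseased": overall(standard, tdi, tds, tdb),
        "pa_healthy": overall(pa_model, thi, ths, thb),
        "pa_diseased": overall(pa_model, tdi, tds, tdb),
    }
    ttest = metrics.compare_methods(
        rep["pa_diseased"].per_image["Overall"].to_numpy(),
        rep["standard_diseased"].per_image["Overall"].to_numpy())
    return {
        "standard_model": standard,
        "pa_model": pa_model,
        "reports": rep,
        "dice": {k: r.overall_mean() for k, r in rep.items()},
        "paired_t": ttest,
        "test_healthy": (thi, ths, tht, thb),
        "test_diseased": (tdi, tds, tdt, tdb),
    }


def run_detection_eval(sublayer_model, test_sets: Sequence[ScanSet]
                       ) -> Dict[str, object]:
    """Rule-based lesion detection scored against ground-truth boxes."""

    detector = RuleBasedDetector(segmenter=sublayer_model)
    detections: List[Detection] = []
    gts: Dict[object, List[BoxAnnotation]] = {}
    presence_correct = 0
    n_images = 0
    ious: List[float] = []
    for si, (images, _subs, _tots, boxes) in enumerate(test_sets):
        for i, (im, b) in enumerate(zip(images, boxes)):
            image_id = (si, i)
            dets = detector.predict(im)
            for d in dets:
                detections.append(Detection(box=d.box, score=d.score,
                                            image_id=image_id))
            top = top_detection(dets)
            presence_correct += (top is not None) == (b is not None)
            n_images += 1
            if b is not None:
                gts[image_id] = [b]
                if top is not None:
                    ious.append(metrics.box_iou(top.box, b))
    summary = metrics.ap_summary(detections, gts)
    return {
        "ap": summary,
        "presence_accuracy": presence_correct / max(n_images, 1),
        "median_iou": float(np.median(ious)) if ious else float("nan"),
        "n_gt_boxes": sum(len(v) for v in gts.values()),
    }


def run_total_retina_eval(seed: int = 7) -> Dict[str, float]:
    """Train the dedicated total-retina segmenter and score it."""

    s = int(seed)
    hi, _, ht, _ = build_scan_set(False, 30, s * 10 + 1)
    di, _, dt, _ = build_scan_set(True, 30, s * 10 + 2)
    vi, _, vt, _ = build_scan_set(False, 6, s * 10 + 3)
    thi, _, tht, _ = build_scan_set(False, 10, s * 10 + 5)
    tdi, _, tdt, _ = build_scan_set(True, 10, s * 10 + 6)
    cfg = segment.TrainConfig(epochs=8, seed=s)
    model, _ = segment.train_total_retina(hi + di, ht + dt, vi, vt, cfg)

    def score(images, totals) -> float:
        preds = [model.predict_labels(im) for im in images]
        return metrics.evaluate_segmentation(preds, totals,
                                             "total").overall_mean()

    healthy = score(thi, tht)
    diseased = score(tdi, tdt)
    return {"healthy": healthy, "diseased": diseased,
            "overall": float(np.mean([healthy, diseased]))}
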