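"""Stage 1: locate the severely affected region as a single box per B-scan.

A region is severely affected where at least one retinal sublayer is
undetectable.  The detector contract is ``fit(images, boxes)`` /
``predict(image) -> [Detection, ...]``; the pipeline keeps the top-scoring
box with confidence >= 0.5 and passes at most one box downstream.

Two implementations are provided:

* :class:`RuleBasedDetector` (the tested default): runs a trained sublayer
  segmenter, audits each column for a sublayer with thickness below
  ``t_min`` pixels, and merges all affected columns into one box whose
  confidence is the affected fraction of its column span.
* :class:`ColumnDetector` (learned): a per-column logistic-regression
  classifier on column profile features, trained on box-annotated scans.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Protocol, Sequence, Tuple

import numpy as np

from .features import column_features
from .types import SUBLAYER_IDS, BoxAnnotation, Detection


class DetectorContract(Protocol):
    """Anything that can be fitted on box-annotated scans and score boxes."""

    def fit(self, images: Sequence[np.ndarray],
            boxes: Sequence[Optional[BoxAnnotation]]) -> "DetectorContract": ...

    def predict(self, image: np.ndarray) -> List[Detection]: ...


def column_integrity_profile(labels: np.ndarray, t_min: int = 1) -> np.ndarray:
    """Boolean per-column flags: True where some sublayer is undetectable.

    A column is affected iff any of the five sublayer classes occupies
    fewer than ``t_min`` pixels in it (default 1 px, i.e. the layer is
    entirely absent).  Expects a 6-class sublayer label map (or argmax of
    a 6-class probability map).
    """

    labels = np.asarray(labels)
    thickness = np.stack([(labels == k).sum(axis=0) for k in SUBLAYER_IDS])
    return (thickness < t_min).any(axis=0)


def merge_single_box(affected: np.ndarray,
                     row_extent: Tuple[int, int]
                     ) -> Optional[Tuple[BoxAnnotation, float]]:
    """Merge all affected columns into one box (or None if none).

    The box spans the min..max affected column and the given retina row
    extent; its confidence is the fraction of columns inside the box that
    are actually flagged (1.0 for a single compact region, lower when
    disjoint regions were merged across a clean gap).
    """

    cols = np.flatnonzero(np.asarray(affected, dtype=bool))
    if cols.size == 0:
        return None
    x0, x1 = int(cols[0]), int(cols[-1]) + 1
    confidence = float(cols.size / (x1 - x0))
    y0, y1 = int(row_extent[0]), int(row_extent[1])
    return BoxAnnotation(x0, x1, y0, y1), confidence


def _band_rows(labels: np.ndarray) -> Tuple[int, int]:
    rows = np.flatnonzero((np.asarray(labels) > 0).any(axis=1))
    if rows.size == 0:
        h = labels.shape[0]
        return h // 3, 2 * h // 3
    return int(rows[0]), int(rows[-1]) + 1


def _filter_short_runs(flags: np.ndarray, min_run: int) -> np.ndarray:
    """Drop affected runs shorter than ``min_run`` columns (noise guard)."""

    flags = np.asarray(flags, dtype=bool).copy()
    if min_run <= 1:
        return flags
    padded = np.concatenate([[False], flags, [False]])
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:])
    for s, e in zip(starts, ends):
        if e - s < min_run:
            flags[s:e] = False
    return flags


@dataclass
class RuleBasedDetector:
    """Segment-then-audit detector over a trained sublayer segmenter.

    ``t_min`` is the thickness threshold (px) below which a layer counts
    as undetectable.  Ground-truth audits use 1 px (a layer truly absent),
    but a trained segmenter smears a few pixels of every class into
    lesion columns, so the default ``"auto"`` scales the threshold with
    axial resolution (2.5% of image height, at least 2 px).  ``min_run``
    suppresses isolated flagged columns caused by segmentation noise.
    """

    segmenter: object                     # fitted sublayer SegmenterContract
    t_min: object = "auto"                # int px, or "auto"
    min_run: int = 8

    def fit(self, images, boxes):  # noqa: D102 - contract no-op
        return self

    def _resolve_t_min(self, height: int) -> int:
        if self.t_min == "auto":
            return max(2, int(round(0.025 * height)))
        return int(self.t_min)

    def predict(self, image: np.ndarray) -> List[Detection]:
        labels = self.segmenter.predict_labels(image)
        t_min = self._resolve_t_min(image.shape[0])
        flags = column_integrity_profile(labels, t_min=t_min)
        flags = _filter_short_runs(flags, self.min_run)
        merged = merge_single_box(flags, _band_rows(labels))
        if merged is None:
            return []
        box, confidence = merged
        return [Detection(box=box, score=confidence)]


@dataclass
class DetectorConfig:
    """Learned-detector schedule: lr 5e-4, 2000 iterations in the first
    loop rising to 3000 by the tenth."""

    lr: float = 5e-4
    base_iterations: int = 2000
    max_iterations: int = 3000
    seed: int = 0

    def iterations_for_loop(self, loop: int) -> int:
        return min(self.base_iterations + 100 * loop, self.max_iterations)


class ColumnDetector:
    """Learned detector: logistic regression on per-column profile features.

    Columns inside the annotated box are positive examples.  At predict
    time, per-column probabilities are thresholded at 0.5, short runs are
    suppressed, and all remaining columns merge into a single box whose
    confidence is the mean column probability inside it.
    """

    def __init__(self, config: Optional[DetectorConfig] = None,
                 min_run: int = 8, loop: int = 0) -> None:
        self.config = config or DetectorConfig()
        self.min_run = min_run
        self.loop = loop
        self._clf = None

    def fit(self, images: Sequence[np.ndarray],
            boxes: Sequence[Optional[BoxAnnotation]]) -> "ColumnDetector":
        from sklearn.linear_model import LogisticRegression

        if len(images) == 0:
            raise ValueError("empty detector training set")
        X, y = [], []
        for img, box in zip(images, boxes):
            feats = column_features(img)
            labels = np.zeros(img.shape[1], dtype=int)
            if box is not None:
                labels[box.x_start:box.x_end] = 1
            X.append(feats)
            y.append(labels)
        Xc = np.concatenate(X)
        yc = np.concatenate(y)
        if yc.max() == yc.min():
            raise ValueError("detector training set has a single class "
                             "(need scans with and without boxes)")
        self._clf = LogisticRegression(
            C=10.0, max_iter=self.config.iterations_for_loop(self.loop),
            random_state=self.config.seed)
        self._clf.fit(Xc, yc)
        return self

    def predict(self, image: np.ndarray) -> List[Detection]:
        if self._clf is None:
            raise RuntimeError("ColumnDetector.predict before fit")
        probs = self._clf.predict_proba(column_features(image))[:, 1]
        flags = _filter_short_runs(probs >= 0.5, self.min_run)
        if not flags.any():
            return []
        cols = np.flatnonzero(flags)
        x0, x1 = int(cols[0]), int(cols[-1]) + 1
        score = float(np.clip(probs[x0:x1].mean(), 0.0, 1.0))
        h = image.shape[0]
        from .features import band_extent

        top, bottom = band_extent(image)
        y0 = int(np.clip(np.floor(top[x0:x1].min()), 0, h - 2))
        y1 = int(np.clip(np.ceil(bottom[x0:x1].max()), y0 + 1, h))
        return [Detection(box=BoxAnnotation(x0, x1, y0, y1), score=score)]


def train_learned_detector(images: Sequence[np.ndarray],
                           boxes: Sequence[Optional[BoxAnnotation]],
                           config: Optional[DetectorConfig] = None,
                           loop: int = 0) -> ColumnDetector:
    """Fit the learned column detector on annotated scans."""

    return ColumnDetector(config=config, loop=loop).fit(images, boxes)


def top_detection(detections: Sequence[Detection],
                  confidence_threshold: float = 0.5) -> Optional[Detection]:
    """Single-box selection rule: best-scoring detection above threshold."""

    kept = [d for d in detections if d.score >= confidence_threshold]
    if not kept:
        return None
    return max(kept, key=lambda d: d.score)
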