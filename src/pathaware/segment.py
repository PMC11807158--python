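"""Total-retina (2-class) and sublayer (6-class) segmentation with standard
or pathology-aware training, plus composed inference.

The segmenter contract is ``forward(image) -> per-pixel class
probabilities``; any trainable model can implement it.  The default
implementation is a pixel-wise multilayer-perceptron classifier (one tanh
hidden layer, 16 units) over engineered column-local features
(:mod:`pathaware.features`).  It is deliberately compact: it trains in
seconds on a CPU, its gradients are written out in closed form against the
exact combined cross-entropy + Dice objective, and — because its features
are column-local — the pathology-aware mask provably isolates training
from everything inside a box's column band.

Training follows the study schedule: Adam, a validation-Dice-monitoring
learning-rate scheduler (decay 0.5, patience 15 epochs), best-on-validation
checkpointing, 15 epochs per loop for the total-retina task and 30 for the
harder sublayer task, batches of 15 images.  In pathology-aware mode the
loss is the masked combined loss with exclusion masks built from the box
annotations; in standard mode the mask is all ones, and the two modes
produce bit-identical parameter trajectories whenever no image has a box.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import losses
from .features import N_PIXEL_FEATURES, pixel_features
from .metrics import dice_score
from .types import (COMPOSED_TOTAL, SUBLAYER_IDS, BoxAnnotation, Detection,
                    LabelMask)


@dataclass
class TrainConfig:
    """Hyperparameters for one training run.

    ``lr`` is the Adam learning rate; the study's published schedule used
    5e-4 with large pretrained convolutional backbones — the compact MLP
    default here needs a larger step (see docs/methods.md).  ``epochs``
    defaults per task (15 total retina, 30 sublayers).  ``loss_mode`` is
    ``"standard"`` (plain combined loss) or ``"pathology_aware"`` (masked
    combined loss with box-derived exclusion masks); ``masked_norm``
    selects the Eq.-style literal 1/N normalization or per-unmasked-pixel
    normalization of the masked cross-entropy.
    """

    lr: float = 0.02
    epochs: int = 15
    batch_size: int = 15            # images per optimization step group
    pixels_per_image: int = 2000    # pixels sampled per image per epoch
    pixel_batch: int = 4096         # pixels per Adam step
    hidden: int = 16
    scheduler_decay: float = 0.5
    scheduler_patience: int = 15    # epochs without val-Dice improvement
    min_lr: float = 1e-5
    loss_mode: str = "standard"     # or "pathology_aware"
    masked_norm: str = "literal"    # or "unmasked"
    include_background_dice: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr <= 0 or self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("hyperparameters must be positive")
        if self.loss_mode not in ("standard", "pathology_aware"):
            raise ValueError(f"unknown loss_mode {self.loss_mode!r}")


class MLPSegmenter:
    """Pixel-wise softmax classifier with one tanh hidden layer.

    ``n_classes`` is 2 (total mode) or 6 (sublayer mode).  ``forward``
    maps an image to an ``(H, W, C)`` probability map whose per-pixel
    class sum is 1.
    """

    architecture = "pixel-mlp-16"

    def __init__(self, n_classes: int, hidden: int = 16, seed: int = 0,
                 n_features: int = N_PIXEL_FEATURES) -> None:
        if n_classes not in (2, 6):
            raise ValueError("n_classes must be 2 (total) or 6 (sublayer)")
        rng = np.random.default_rng(seed)
        lim1 = np.sqrt(6.0 / (n_features + hidden))
        lim2 = np.sqrt(6.0 / (hidden + n_classes))
        self.n_classes = n_classes
        self.hidden = hidden
        self.params: Dict[str, np.ndarray] = {
            "W1": rng.uniform(-lim1, lim1, (n_features, hidden)),
            "b1": np.zeros(hidden),
            "W2": rng.uniform(-lim2, lim2, (hidden, n_classes)),
            "b2": np.zeros(n_classes),
        }

    # -- forward ----------------------------------------------------------

    def _logits(self, X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        h = np.tanh(X @ self.params["W1"] + self.params["b1"])
        return h @ self.params["W2"] + self.params["b2"], h

    @staticmethod
    def _softmax(z: np.ndarray) -> np.ndarray:
        z = z - z.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)

    def forward_features(self, X: np.ndarray) -> np.ndarray:
        z, _ = self._logits(X)
        return self._softmax(z)

    def forward(self, image: np.ndarray) -> np.ndarray:
        """Image -> ``(H, W, n_classes)`` probability map."""

        h, w = image.shape
        X = pixel_features(image).reshape(-1, N_PIXEL_FEATURES)
        return self.forward_features(X).reshape(h, w, self.n_classes)

    def predict_labels(self, image: np.ndarray) -> np.ndarray:
        return self.forward(image).argmax(axis=-1)

    # -- persistence ------------------------------------------------------

    def save(self, path: Path) -> None:
        np.savez(path, n_classes=self.n_classes, hidden=self.hidden,
                 **self.params)

    @classmethod
    def load(cls, path: Path) -> "MLPSegmenter":
        data = np.load(path)
        model = cls(int(data["n_classes"]), hidden=int(data["hidden"]))
        model.params = {k: data[k] for k in ("W1", "b1", "W2", "b2")}
        return model


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _loss_gradients(model: MLPSegmenter, X: np.ndarray, y: np.ndarray,
                    m: np.ndarray, config: TrainConfig
                    ) -> Tuple[Dict[str, np.ndarray], float]:
    """Closed-form gradient of the masked combined loss on a pixel batch.

    The mask enters every sum, so rows with ``m == 0`` contribute exactly
    zero to the loss and to every parameter gradient.
    """

    B, C = X.shape[0], model.n_classes
    z, hact = model._logits(X)
    p = model._softmax(z)
    onehot = np.eye(C)[y]

    # cross-entropy term
    if config.masked_norm == "literal":
        n_ce = float(B)
    else:
        n_ce = max(float(m.sum()), 1.0)
    p_true = np.clip(p[np.arange(B), y], losses.EPS, 1.0)
    ce = float((-np.log(p_true) * m).sum() / n_ce)
    dz = m[:, None] * (p - onehot) / n_ce

    # soft Dice term, one-vs-rest averaged over non-background classes
    start = 0 if config.include_background_dice else 1
    dice_terms: List[float] = []
    gp = np.zeros_like(p)
    active = []
    for c in range(start, C):
        sy = float((m * onehot[:, c]).sum())
        sp = float((m * p[:, c]).sum())
        den = sy + sp
        if den <= losses.EPS:
            continue
        num = float((m * onehot[:, c] * p[:, c]).sum())
        dice_terms.append(1.0 - 2.0 * num / den)
        active.append((c, num, den))
    K = max(len(active), 1)
    for c, num, den in active:
        gp[:, c] = -2.0 * m * (onehot[:, c] * den - num) / (K * den * den)
    dice = float(np.mean(dice_terms)) if dice_terms else 0.0
    dz += p * (gp - (gp * p).sum(axis=1, keepdims=True))

    dW2 = hact.T @ dz
    db2 = dz.sum(axis=0)
    dh = dz @ model.params["W2"].T
    dpre = dh * (1.0 - hact ** 2)
    dW1 = X.T @ dpre
    db1 = dpre.sum(axis=0)
    grads = {"W1": dW1, "b1": db1, "W2": dW2, "b2": db2}
    return grads, ce + dice


class _Adam:
    def __init__(self, params: Dict[str, np.ndarray], lr: float) -> None:
        self.lr = lr
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: Dict[str, np.ndarray],
             grads: Dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k in params:
            self.m[k] = b1 * self.m[k] + (1 - b1) * grads[k]
            self.v[k] = b2 * self.v[k] + (1 - b2) * grads[k] ** 2
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)


def _validation_dice(model: MLPSegmenter,
                     feats: Sequence[np.ndarray],
                     labels: Sequence[np.ndarray],
                     masks: Sequence[Optional[np.ndarray]]) -> float:
    """Mean over images of the class-averaged Dice (background excluded),
    restricted to unmasked pixels when an exclusion mask is present."""

    scores = []
    for X, lab, m in zip(feats, labels, masks):
        h, w = lab.shape
        pred = model.forward_features(
            X.reshape(-1, X.shape[-1])).argmax(axis=-1).reshape(h, w)
        region = None if m is None else m.astype(bool)
        per_class = [dice_score(pred, lab, c, region)
                     for c in range(1, model.n_classes)]
        per_class = [d for d in per_class if not np.isnan(d)]
        if per_class:
            scores.append(float(np.mean(per_class)))
    return float(np.mean(scores)) if scores else 0.0


def train_segmenter(train_images: Sequence[np.ndarray],
                    train_labels: Sequence[np.ndarray],
                    val_images: Sequence[np.ndarray],
                    val_labels: Sequence[np.ndarray],
                    n_classes: int,
                    config: TrainConfig,
                    train_boxes: Optional[Sequence[Optional[BoxAnnotation]]] = None,
                    val_boxes: Optional[Sequence[Optional[BoxAnnotation]]] = None,
                    ) -> Tuple[MLPSegmenter, Dict[str, List[float]]]:
    """Fit a segmenter; return (best-on-validation model, training history).

    ``history["val_dice"]`` holds one entry per epoch.  In
    ``pathology_aware`` mode the per-image exclusion masks are built from
    ``train_boxes`` (missing/None boxes give all-ones masks); standard
    mode ignores boxes entirely.  Deterministic given ``config.seed``.
    """

    if len(train_images) == 0:
        raise ValueError("empty training set")
    for lab in train_labels:
        if lab.max() >= n_classes:
            raise ValueError("label exceeds configured class count")
    present = set()
    for lab in train_labels:
        present |= set(np.unique(lab))
    if len(present) < 2:
        raise ValueError("training labels contain a single class")

    rng = np.random.default_rng(config.seed)
    model = MLPSegmenter(n_classes, hidden=config.hidden, seed=config.seed)
    opt = _Adam(model.params, config.lr)

    use_masks = config.loss_mode == "pathology_aware" and train_boxes is not None

    def exclusion(i: int, shape) -> np.ndarray:
        if use_masks and train_boxes[i] is not None:
            return losses.box_to_mask(train_boxes[i], shape)
        return np.ones(shape)

    feats = [pixel_features(img) for img in train_images]
    masks = [exclusion(i, lab.shape) for i, lab in enumerate(train_labels)]
    vfeats = [pixel_features(img) for img in val_images]
    if val_boxes is not None:
        vmasks: List[Optional[np.ndarray]] = [
            None if b is None else losses.box_to_mask(b, lab.shape)
            for b, lab in zip(val_boxes, val_labels)]
    else:
        vmasks = [None] * len(val_labels)

    fully_masked = [i for i, m in enumerate(masks) if m.sum() == 0]
    history: Dict[str, List[float]] = {"val_dice": [], "train_loss": [],
                                       "lr": []}
    if fully_masked:
        history["fully_masked_images"] = [float(i) for i in fully_masked]

    best_dice = -1.0
    best_params = copy.deepcopy(model.params)
    since_improvement = 0

    for _epoch in range(config.epochs):
        order = rng.permutation(len(train_images))
        epoch_losses = []
        for gstart in range(0, len(order), config.batch_size):
            group = order[gstart:gstart + config.batch_size]
            Xs, ys, ms = [], [], []
            for i in group:
                h, w = train_labels[i].shape
                idx = rng.choice(h * w, size=min(config.pixels_per_image,
                                                 h * w), replace=False)
                Xs.append(feats[i].reshape(-1, N_PIXEL_FEATURES)[idx])
                ys.append(train_labels[i].reshape(-1)[idx])
                ms.append(masks[i].reshape(-1)[idx])
            X = np.concatenate(Xs)
            y = np.concatenate(ys)
            m = np.concatenate(ms)
            perm = rng.permutation(len(X))
            for bstart in range(0, len(X), config.pixel_batch):
                sl = perm[bstart:bstart + config.pixel_batch]
                grads, loss = _loss_gradients(model, X[sl], y[sl], m[sl],
                                              config)
                opt.step(model.params, grads)
                epoch_losses.append(loss)

        vdice = _validation_dice(model, vfeats, val_labels, vmasks)
        history["val_dice"].append(vdice)
        history["train_loss"].append(float(np.mean(epoch_losses)))
        history["lr"].append(opt.lr)

        if vdice > best_dice + 1e-6:
            best_dice = vdice
            best_params = copy.deepcopy(model.params)
            since_improvement = 0
        else:
            since_improvement += 1
            if since_improvement >= config.scheduler_patience:
                opt.lr = max(opt.lr * config.scheduler_decay, config.min_lr)
                since_improvement = 0

    model.params = best_params
    return model, history


def train_total_retina(train_images, train_labels, val_images, val_labels,
                       config: Optional[TrainConfig] = None
                       ) -> Tuple[MLPSegmenter, Dict[str, List[float]]]:
    """2-class (background / total retina) training with the standard loss.

    Default schedule: 15 epochs per loop.
    """

    config = config or TrainConfig(epochs=15)
    return train_segmenter(train_images, train_labels, val_images,
                           val_labels, n_classes=2, config=config)


def train_sublayers(train_images, train_labels, val_images, val_labels,
                    train_boxes: Optional[Sequence[Optional[BoxAnnotation]]] = None,
                    val_boxes: Optional[Sequence[Optional[BoxAnnotation]]] = None,
                    config: Optional[TrainConfig] = None
                    ) -> Tuple[MLPSegmenter, Dict[str, List[float]]]:
    """6-class sublayer training, standard or pathology-aware.

    In pathology-aware mode the exclusion masks come from the annotated
    ground-truth boxes; sublayer labels are only trusted outside them.
    Default schedule: 30 epochs per loop.
    """

    config = config or TrainConfig(epochs=30, loss_mode="pathology_aware")
    return train_segmenter(train_images, train_labels, val_images,
                           val_labels, n_classes=6, config=config,
                           train_boxes=train_boxes, val_boxes=val_boxes)


# ---------------------------------------------------------------------------
# Composed inference
# ---------------------------------------------------------------------------

def compose_prediction(image: np.ndarray,
                       detection: Optional[Detection],
                       total_model: MLPSegmenter,
                       sublayer_model: MLPSegmenter) -> LabelMask:
    """Final composed labels: sublayers outside the box, total retina inside.

    Inside the detected box's column band, retina pixels carry the
    composed-total code (6); outside, pixels carry the sublayer argmax.
    With no detection the output is the pure sublayer prediction.
    """

    sub = sublayer_model.predict_labels(image)
    if detection is None:
        return LabelMask(sub, "composed")
    total = total_model.predict_labels(image)
    out = sub.copy()
    x0, x1 = detection.box.x_start, detection.box.x_end
    out[:, x0:x1] = np.where(total[:, x0:x1] > 0, COMPOSED_TOTAL, 0)
    return LabelMask(out, "composed")


def aggregate_sublayers_to_total(mask: LabelMask) -> LabelMask:
    """Collapse sublayer (or composed) labels to background / total retina."""

    if mask.mode not in ("sublayer", "composed"):
        raise ValueError("expected sublayer or composed input")
    return LabelMask((mask.labels > 0).astype(np.int64), "total")
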