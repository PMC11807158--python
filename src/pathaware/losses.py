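"""Combined cross-entropy + Dice losses and their pathology-aware, region-
masked counterparts.

Standard training minimizes

    loss    = loss_ce + loss_dc
    loss_ce = -(1/N) sum_i y_i log(yhat_i)
    loss_dc = 1 - 2 sum_i y_i yhat_i / (sum_i y_i + sum_i yhat_i)

with ``y`` the one-hot ground truth, ``yhat`` the predicted probability and
``N`` the number of pixels in the batch.  The pathology-aware variants
insert a binary exclusion mask ``m`` (0 inside the detected box's
full-height column band, 1 elsewhere):

    loss_pa,ce = -(1/N) sum_i m_i y_i log(m_i yhat_i)
    loss_pa,dc = 1 - 2 sum_i m_i y_i yhat_i
                     / (sum_i m_i y_i + sum_i m_i yhat_i)
    loss_pa    = loss_pa,ce + loss_pa,dc

with the convention 0*log(0) := 0, implemented by restricting every sum to
unmasked pixels, so pixels inside the box contribute exactly zero to the
value *and* to any gradient.  With ``m == 1`` everywhere the masked losses
reduce bit-for-bit to the standard ones.

Normalization of the masked cross-entropy: the literal form divides by the
full pixel count ``N`` (default, ``masked_norm="literal"``), so the loss
shrinks as the box grows; ``masked_norm="unmasked"`` divides by
``sum(m)`` instead.  Multi-class Dice is computed one-vs-rest per class and
averaged over the classes present; background is included in the
cross-entropy but excluded from the Dice average by default.

All functions accept probabilities of shape ``(..., C)`` (class-last),
integer labels of the matching leading shape, and a mask of the leading
shape; leading dimensions may include a batch axis.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .types import BoxAnnotation, LossValue

EPS = 1e-7  # probability clamp for numerical safety


def box_to_mask(box: Optional[BoxAnnotation], shape) -> np.ndarray:
    """Build the full-height exclusion mask for ``shape`` = (H, W).

    Zero on every row of columns ``[x_start, x_end)`` — the box height is
    extended to span the whole image — one elsewhere.  ``box=None`` yields
    an all-ones mask (nothing excluded).
    """

    h, w = shape
    mask = np.ones((h, w), dtype=float)
    if box is not None:
        box.validate_within((h, w))
        mask[:, box.x_start:box.x_end] = 0.0
    return mask


def _check(probs: np.ndarray, labels: np.ndarray,
           mask: Optional[np.ndarray]) -> None:
    probs = np.asarray(probs)
    labels = np.asarray(labels)
    if probs.shape[:-1] != labels.shape:
        raise ValueError(f"probs {probs.shape} vs labels {labels.shape}")
    sums = probs.sum(axis=-1)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("per-pixel class probabilities must sum to 1")
    if mask is not None and np.asarray(mask).shape != labels.shape:
        raise ValueError("mask shape must match labels")


def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    return np.eye(n_classes)[labels]


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-likelihood of the true class over all pixels."""

    _check(probs, labels, None)
    p_true = np.take_along_axis(np.asarray(probs, dtype=float),
                                labels[..., None], axis=-1)[..., 0]
    return float(-np.log(np.clip(p_true, EPS, 1.0)).mean())


def masked_cross_entropy(probs: np.ndarray, labels: np.ndarray,
                         mask: np.ndarray,
                         masked_norm: str = "literal") -> float:
    """Cross-entropy restricted to unmasked pixels.

    ``masked_norm="literal"`` divides by the total pixel count N;
    ``"unmasked"`` divides by the number of unmasked pixels.  Reduces to
    ``cross_entropy`` exactly when the mask is all ones.
    """

    _check(probs, labels, mask)
    mask = np.asarray(mask, dtype=float)
    p_true = np.take_along_axis(np.asarray(probs, dtype=float),
                                labels[..., None], axis=-1)[..., 0]
    nll = -np.log(np.clip(p_true, EPS, 1.0)) * mask
    if masked_norm == "literal":
        denom = float(mask.size)
    elif masked_norm == "unmasked":
        denom = float(mask.sum())
        if denom == 0.0:
            return 0.0
    else:
        raise ValueError(f"unknown masked_norm {masked_norm!r}")
    return float(nll.sum() / denom)


def _dice_per_class(probs: np.ndarray, labels: np.ndarray,
                    mask: Optional[np.ndarray],
                    include_background: bool) -> float:
    probs = np.asarray(probs, dtype=float)
    n_classes = probs.shape[-1]
    y = _one_hot(np.asarray(labels), n_classes)
    if mask is not None:
        m = np.asarray(mask, dtype=float)[..., None]
        y = y * m
        probs = probs * m
    start = 0 if include_background else 1
    losses = []
    for c in range(start, n_classes):
        sy = y[..., c].sum()
        sp = probs[..., c].sum()
        if sy + sp <= EPS:          # class absent from both: skip
            continue
        losses.append(1.0 - 2.0 * (y[..., c] * probs[..., c]).sum() / (sy + sp))
    if not losses:
        return 0.0
    return float(np.mean(losses))


def dice_loss(probs: np.ndarray, labels: np.ndarray,
              include_background: bool = False) -> float:
    """Soft Dice loss in [0, 1]: one-vs-rest per class, class-averaged."""

    _check(probs, labels, None)
    return _dice_per_class(probs, labels, None, include_background)


def masked_dice_loss(probs: np.ndarray, labels: np.ndarray, mask: np.ndarray,
                     include_background: bool = False) -> float:
    """Dice loss over unmasked pixels only.

    A class whose masked denominator vanishes contributes 0 by convention.
    Reduces to ``dice_loss`` exactly when the mask is all ones.
    """

    _check(probs, labels, mask)
    return _dice_per_class(probs, labels, mask, include_background)


def combined_loss(probs: np.ndarray, labels: np.ndarray,
                  mask: Optional[np.ndarray] = None,
                  masked_norm: str = "literal",
                  include_background_dice: bool = False) -> LossValue:
    """Combined CE + Dice; ``mask=None`` routes to the standard loss."""

    if mask is None:
        return LossValue(ce=cross_entropy(probs, labels),
                         dice=dice_loss(probs, labels,
                                        include_background_dice))
    return LossValue(
        ce=masked_cross_entropy(probs, labels, mask, masked_norm),
        dice=masked_dice_loss(probs, labels, mask, include_background_dice))
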