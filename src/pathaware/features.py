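"""Column-local image features for the pixel-classifier segmenter and the
column-profile lesion detector.

Every feature of a pixel depends only on pixels in the *same column*
(axial 1-D smoothing, per-column band detection, per-column statistics).
This locality is deliberate: the pathology-aware loss guarantees that
nothing inside a detected box influences training, and column-local
features extend that guarantee from the loss to the whole input pipeline —
altering the image inside the box's column band cannot change any feature,
prediction or gradient outside it.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d

N_PIXEL_FEATURES = 10


def _axial_smooth(image: np.ndarray, sigma: float) -> np.ndarray:
    return gaussian_filter1d(image, sigma=sigma, axis=0, mode="nearest")


def band_extent(image: np.ndarray, sigma: float = 4.0,
                rel_threshold: float = 0.35
                ) -> Tuple[np.ndarray, np.ndarray]:
    """Estimate the retina band per column: (top rows, bottom rows).

    Threshold = low decile + ``rel_threshold`` * (99th percentile - low
    decile) of the axially smoothed column; top/bottom are the first/last
    suprathreshold rows.  Columns with no suprathreshold pixel get
    ``top == bottom`` (zero thickness) at mid-height.
    """

    h, w = image.shape
    sm = _axial_smooth(image, sigma)
    lo = np.percentile(sm, 10, axis=0)
    hi = np.percentile(sm, 99, axis=0)
    thr = lo + rel_threshold * np.maximum(hi - lo, 1e-6)
    above = sm > thr[None, :]
    any_above = above.any(axis=0)
    top = np.where(any_above, above.argmax(axis=0), h // 2).astype(float)
    bottom = np.where(any_above, h - above[::-1].argmax(axis=0), h // 2).astype(float)
    return top, bottom


def pixel_features(image: np.ndarray) -> np.ndarray:
    """Per-pixel feature stack, shape ``(H, W, N_PIXEL_FEATURES)``.

    Features: raw intensity; axially smoothed intensity at sigma 2 and 6;
    axial gradient of the sigma-2 smoothing; normalized row; depth below
    the band top (rows / H); fractional depth within the band (clipped);
    band thickness / H; mean band intensity; cumulative-reflectance depth
    coordinate (fraction of the column's integrated suprabackground signal
    above the pixel — a smooth, speckle-robust depth axis).
    """

    image = np.asarray(image, dtype=float)
    h, w = image.shape
    g2 = _axial_smooth(image, 2.0)
    g6 = _axial_smooth(image, 6.0)
    grad = np.gradient(g2, axis=0)
    rows = np.broadcast_to(np.arange(h, dtype=float)[:, None], (h, w))

    top, bottom = band_extent(image)
    thickness = np.maximum(bottom - top, 1.0)
    depth = (rows - top[None, :]) / h
    frac = np.clip((rows - top[None, :]) / thickness[None, :], -0.2, 1.2)

    band = (rows >= top[None, :]) & (rows < bottom[None, :])
    band_sum = np.where(band, image, 0.0).sum(axis=0)
    band_n = np.maximum(band.sum(axis=0), 1)
    band_mean = band_sum / band_n

    lo = np.percentile(g2, 10, axis=0)
    signal = np.maximum(g2 - lo[None, :], 0.0)
    cum = np.cumsum(signal, axis=0)
    total = np.maximum(cum[-1, :], 1e-6)
    cumfrac = cum / total[None, :]

    return np.stack([
        image, g2, g6, grad * 10.0,
        rows / h, depth, frac,
        np.broadcast_to((thickness / h)[None, :], (h, w)),
        np.broadcast_to(band_mean[None, :], (h, w)),
        cumfrac,
    ], axis=-1)


def column_features(image: np.ndarray, n_bins: int = 12) -> np.ndarray:
    """Per-column feature vectors, shape ``(W, n_bins + 2)``.

    Band thickness / H, mean band intensity, and the smoothed intensity
    profile resampled at ``n_bins`` equally spaced fractional depths
    within the band.  Used by the learned column-classifier detector.
    """

    image = np.asarray(image, dtype=float)
    h, w = image.shape
    g2 = _axial_smooth(image, 2.0)
    top, bottom = band_extent(image)
    thickness = np.maximum(bottom - top, 1.0)

    rows = np.arange(h, dtype=float)[:, None]
    band = (rows >= top[None, :]) & (rows < bottom[None, :])
    band_mean = np.where(band, image, 0.0).sum(axis=0) / np.maximum(
        band.sum(axis=0), 1)

    fracs = np.linspace(0.05, 0.95, n_bins)
    profile = np.empty((w, n_bins))
    for c in range(w):
        sample_rows = np.clip(top[c] + fracs * thickness[c], 0, h - 1)
        profile[c] = np.interp(sample_rows, np.arange(h), g2[:, c])
    return np.concatenate([(thickness / h)[:, None],
                           band_mean[:, None], profile], axis=1)
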