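"""Shared domain containers for B-scans, label masks, boxes and detections.

Conventions used throughout the package:

* arrays are ``(height, width)`` with row 0 at the top (vitreous side);
* all pixel intervals are 0-based and half-open ``[start, end)``;
* grayscale images live in ``[0, 1]`` as floats.

Label encodings
---------------
``sublayer`` mode : 0=background, 1=IR, 2=ONL, 3=PR-IS, 4=PR-OS, 5=RPE.
``total`` mode    : 0=background, 1=total retina.
``composed`` mode : sublayer codes outside the detected box plus 6=total
                    retina inside the box's column band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

BACKGROUND = 0
SUBLAYER_IDS: Tuple[int, ...] = (1, 2, 3, 4, 5)
SUBLAYER_NAMES = {1: "IR", 2: "ONL", 3: "PR-IS", 4: "PR-OS", 5: "RPE"}
TOTAL_RETINA = 1          # label of the retina band in total mode
COMPOSED_TOTAL = 6        # label of the in-box retina band in composed mode

N_SUBLAYER_CLASSES = 6    # background + 5 sublayers
N_TOTAL_CLASSES = 2       # background + total retina


@dataclass(frozen=True)
class BoxAnnotation:
    """One orthogonal box marking a severely affected region.

    Columns ``[x_start, x_end)`` and rows ``[y_start, y_end)``, half-open.
    At most one box exists per B-scan (small damaged regions are merged
    into a single enclosing box).
    """

    x_start: int
    x_end: int
    y_start: int
    y_end: int

    def __post_init__(self) -> None:
        if not (self.x_start < self.x_end and self.y_start < self.y_end):
            raise ValueError(f"degenerate box {self}")
        if self.x_start < 0 or self.y_start < 0:
            raise ValueError(f"negative box coordinates {self}")

    @property
    def width(self) -> int:
        return self.x_end - self.x_start

    @property
    def height(self) -> int:
        return self.y_end - self.y_start

    @property
    def area(self) -> int:
        return self.width * self.height

    def validate_within(self, shape: Tuple[int, int]) -> None:
        """Raise if the box is not contained in an image of ``shape`` (H, W)."""
        h, w = shape
        if self.x_end > w or self.y_end > h:
            raise ValueError(f"box {self} exceeds image shape {(h, w)}")

    def to_xywh(self) -> Tuple[float, float, float, float]:
        """COCO-style ``[x, y, width, height]``."""
        return (float(self.x_start), float(self.y_start),
                float(self.width), float(self.height))

    @classmethod
    def from_xywh(cls, xywh: Sequence[float]) -> "BoxAnnotation":
        x, y, w, h = xywh
        return cls(int(round(x)), int(round(x + w)),
                   int(round(y)), int(round(y + h)))


@dataclass(frozen=True)
class Detection:
    """A scored box prediction for one image."""

    box: BoxAnnotation
    score: float
    image_id: object = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"confidence {self.score} outside [0, 1]")


@dataclass
class BScan:
    """One 2-D OCT cross-section with provenance metadata."""

    image: np.ndarray
    patient_id: str = ""
    site_id: str = ""
    eye: str = "OD"
    visit: int = 0
    slice_index: int = 0

    def __post_init__(self) -> None:
        img = np.asarray(self.image, dtype=float)
        if img.ndim != 2:
            raise ValueError("B-scan image must be 2-D (height, width)")
        if img.min() < -1e-9 or img.max() > 1 + 1e-9:
            raise ValueError("B-scan intensities must lie in [0, 1]")
        if self.eye not in ("OD", "OS"):
            raise ValueError(f"eye must be OD or OS, got {self.eye!r}")
        self.image = img

    @property
    def shape(self) -> Tuple[int, int]:
        return self.image.shape  # type: ignore[return-value]


_MODE_CLASSES = {
    "sublayer": set(range(6)),
    "total": {0, 1},
    "composed": set(range(7)),
}


@dataclass
class LabelMask:
    """Per-pixel integer class map in one of the declared modes."""

    labels: np.ndarray
    mode: str = "sublayer"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label mask must be 2-D")
        if self.mode not in _MODE_CLASSES:
            raise ValueError(f"unknown mode {self.mode!r}")
        extra = set(np.unique(self.labels)) - _MODE_CLASSES[self.mode]
        if extra:
            raise ValueError(f"labels {sorted(extra)} invalid for mode {self.mode!r}")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]


@dataclass
class LossValue:
    """Combined loss with its cross-entropy and Dice components."""

    ce: float
    dice: float

    @property
    def total(self) -> float:
        return self.ce + self.dice

    def __float__(self) -> float:
        return float(self.total)
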