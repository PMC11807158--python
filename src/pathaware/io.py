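"""File formats: grayscale PNGs, indexed-PNG label masks, COCO-style box
JSON and CSV manifests."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from PIL import Image

from .types import BoxAnnotation, LabelMask

# palette: background black, then 6 distinct colors for classes 1..6
_PALETTE = [
    (0, 0, 0), (255, 214, 0), (26, 35, 126), (211, 47, 47),
    (56, 142, 60), (0, 188, 212), (158, 158, 158),
]


def save_image(path: Path, image: np.ndarray) -> None:
    """Write a [0, 1] float image as 8-bit grayscale PNG."""

    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    Image.fromarray((arr * 255.0 + 0.5).astype(np.uint8), mode="L").save(path)


def load_image(path: Path) -> np.ndarray:
    """Read a grayscale PNG/TIFF back to a [0, 1] float array."""

    with Image.open(path) as im:
        arr = np.asarray(im.convert("I")).astype(float)
    scale = 65535.0 if arr.max() > 255 else 255.0
    return arr / scale


def save_mask(path: Path, mask: LabelMask) -> None:
    """Write a label mask as an indexed (palette) PNG, one index per class."""

    im = Image.fromarray(mask.labels.astype(np.uint8), mode="P")
    flat = [v for rgb in _PALETTE for v in rgb]
    im.putpalette(flat + [0] * (768 - len(flat)))
    im.save(path)
    # stash the mode next to the file so a round trip restores it
    Path(str(path) + ".mode").write_text(mask.mode)


def load_mask(path: Path, mode: Optional[str] = None) -> LabelMask:
    with Image.open(path) as im:
        labels = np.asarray(im).astype(np.int64)
    if mode is None:
        sidecar = Path(str(path) + ".mode")
        mode = sidecar.read_text().strip() if sidecar.exists() else "sublayer"
    return LabelMask(labels, mode)


def save_coco_boxes(path: Path,
                    boxes: Mapping[str, Optional[BoxAnnotation]],
                    image_shape: Tuple[int, int]) -> None:
    """Write boxes as COCO-style JSON (one 'lesion' category, xywh floats).

    ``boxes`` maps scan id -> box or None (None = image listed, no
    annotation).
    """

    h, w = image_shape
    images, annotations = [], []
    for i, (scan_id, box) in enumerate(sorted(boxes.items())):
        images.append({"id": i, "file_name": scan_id, "height": h, "width": w})
        if box is not None:
            annotations.append({
                "id": len(annotations),
                "image_id": i,
                "category_id": 1,
                "bbox": list(box.to_xywh()),
                "area": float(box.area),
                "iscrowd": 0,
            })
    doc = {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": 1, "name": "severely_affected_region"}],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_coco_boxes(path: Path) -> Dict[str, Optional[BoxAnnotation]]:
    doc = json.loads(Path(path).read_text())
    id_to_name = {im["id"]: im["file_name"] for im in doc["images"]}
    out: Dict[str, Optional[BoxAnnotation]] = {n: None for n in id_to_name.values()}
    for ann in doc["annotations"]:
        out[id_to_name[ann["image_id"]]] = BoxAnnotation.from_xywh(ann["bbox"])
    return out


def load_manifest(path: Path) -> pd.DataFrame:
    return pd.read_csv(path)


def manifest_hash(manifest: pd.DataFrame) -> str:
    """Stable content hash of a manifest (order-sensitive)."""

    import hashlib

    csv = manifest.to_csv(index=False).encode()
    return hashlib.sha256(csv).hexdigest()
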