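"""Synthetic layered-retina B-scan phantoms with degeneration lesions.

The generator emulates the geometry of a macular OCT cross-section: six
smooth boundaries (ILM, OPL-inner, ELM, EZ-posterior, RPE-inner, choroid-
inner) delimiting five sublayers (IR, ONL, PR-IS, PR-OS, RPE) on a dark
background, with a foveal dip of the inner surface, gentle low-frequency
undulation of the whole band, multiplicative speckle plus additive Gaussian
noise, and — in diseased eyes — outer-layer thinning and focal lesions in
which at least one sublayer vanishes entirely.

A column in which any sublayer has zero thickness is "severely affected";
all such columns of a scan are enclosed in one orthogonal box (disjoint
damaged regions are merged into a single larger box).  Sublayer ground
truth is undefined inside the box: training and evaluation exclude it.

Disease severity ``s`` in [0, 1] acts in three ways:

* global thinning of the outer layers (ONL, PR-IS, PR-OS and mildly RPE),
* brightening of the ONL (hyper-reflective change),
* above an onset threshold, focal lesion spans whose width grows with
  ``s`` and inside which the photoreceptor layers collapse completely.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import (BACKGROUND, SUBLAYER_IDS, SUBLAYER_NAMES, TOTAL_RETINA,
                    BoxAnnotation, LabelMask)

# Fractions of image height for the six mean boundary depths (top to bottom).
# Band spans ~0.28 H .. 0.73 H; layer shares of the band:
# IR 40%, ONL 23%, PR-IS 10%, PR-OS 12%, RPE 15%.
_DEFAULT_BOUNDARY_FRACTIONS = (0.28, 0.46, 0.5635, 0.6085, 0.6625, 0.73)

# Mean gray level of background + each sublayer (IR, ONL, PR-IS, PR-OS, RPE).
_DEFAULT_INTENSITIES = (0.05, 0.45, 0.18, 0.55, 0.70, 0.85)

# How strongly the foveal dip displaces each boundary (decays with depth).
_DIP_WEIGHTS = (1.0, 0.60, 0.30, 0.15, 0.05, 0.0)

# Severity -> per-layer thickness multiplier slope (layer id -> slope).
_THINNING_SLOPES = {1: 0.0, 2: 0.45, 3: 0.50, 4: 0.40, 5: 0.15}

# Severity -> ONL brightening (adds to the ONL mean gray level).
_ONL_BRIGHTENING = 0.30


@dataclass(frozen=True)
class Undulation:
    """Low-frequency boundary undulation parameters.

    ``amplitude`` (px) and ``cycles`` shape a shared sinusoidal displacement
    of the whole band; ``thickness_amplitude`` modulates the band thickness
    multiplicatively (the same factor for every layer, so fractional layer
    depths stay constant across columns in lesion-free scans).
    """

    amplitude: float = 8.0
    cycles: float = 2.0
    thickness_amplitude: float = 0.04


@dataclass(frozen=True)
class FovealDip:
    """Central depression of the inner retinal surface.

    ``center`` column (None = image center), Gaussian ``width`` as a
    fraction of image width, ``depth`` in px (None = 5% of height).
    """

    center: Optional[float] = None
    width: float = 0.12
    depth: Optional[float] = None


@dataclass(frozen=True)
class Noise:
    """Speckle + detector noise.

    ``speckle_looks`` is the shape of a unit-mean gamma multiplier (larger =
    smoother; None disables speckle); ``gaussian_sigma`` is the additive
    noise s.d.
    """

    speckle_looks: Optional[float] = 10.0
    gaussian_sigma: float = 0.01


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters for one synthetic B-scan."""

    width: int = 1024
    height: int = 496
    boundary_count: int = 6
    base_depths: Optional[Tuple[float, ...]] = None
    undulation: Undulation = field(default_factory=Undulation)
    foveal_dip: FovealDip = field(default_factory=FovealDip)
    layer_intensities: Tuple[float, ...] = _DEFAULT_INTENSITIES
    noise: Noise = field(default_factory=Noise)
    severity: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.boundary_count != 6:
            raise ValueError("exactly 6 boundaries (5 sublayers) are supported")
        if len(self.layer_intensities) != 6:
            raise ValueError("layer_intensities must have 6 entries (bg + 5)")
        if any(not 0.0 <= v <= 1.0 for v in self.layer_intensities):
            raise ValueError("intensities must lie in [0, 1]")
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError("severity must lie in [0, 1]")
        depths = self.resolved_depths()
        if list(depths) != sorted(depths):
            raise ValueError("base_depths must increase top to bottom")
        if depths[-1] > self.height or depths[0] < 0:
            raise ValueError("base_depths must lie within the image height")

    def resolved_depths(self) -> Tuple[float, ...]:
        if self.base_depths is not None:
            return tuple(float(d) for d in self.base_depths)
        return tuple(f * self.height for f in _DEFAULT_BOUNDARY_FRACTIONS)


@dataclass(frozen=True)
class LesionSpec:
    """Focal degeneration: layers removed inside column spans.

    ``column_spans`` are half-open ``[start, end)`` intervals;
    ``absent_layers`` names the sublayers that collapse (IR never does);
    ``severity`` scales the collapse (1 = complete loss, emitting a box).
    """

    column_spans: Tuple[Tuple[int, int], ...]
    absent_layers: Tuple[str, ...] = ("PR-IS", "PR-OS")
    debris_intensity: float = 0.75
    debris_density: float = 0.15
    severity: float = 1.0

    def __post_init__(self) -> None:
        for start, end in self.column_spans:
            if start >= end or start < 0:
                raise ValueError(f"invalid span [{start}, {end})")
        valid = set(SUBLAYER_NAMES.values()) - {"IR"}
        if self.column_spans and not self.absent_layers:
            raise ValueError("a lesion span must remove at least one layer")
        bad = set(self.absent_layers) - valid
        if bad:
            raise ValueError(f"cannot remove layers {sorted(bad)}")
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError("severity must lie in [0, 1]")

    def absent_ids(self) -> Tuple[int, ...]:
        name_to_id = {v: k for k, v in SUBLAYER_NAMES.items()}
        return tuple(sorted(name_to_id[n] for n in self.absent_layers))


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, stream])


def generate_boundaries(spec: PhantomSpec) -> np.ndarray:
    """Return the six boundary curves as a ``(6, width)`` float array.

    Boundaries are smooth (a shared sinusoid plus a Gaussian foveal dip),
    strictly ordered top to bottom at every column, and reproducible from
    ``spec.seed``.  Disease severity thins the outer layers globally.

    Raises ``ValueError`` if the dip/undulation would violate ordering.
    """

    w, h = spec.width, spec.height
    depths = np.asarray(spec.resolved_depths())
    base_thickness = np.diff(depths)  # 5 layer thicknesses

    rng = _rng(spec.seed, 0)
    x = np.arange(w, dtype=float)

    und = spec.undulation
    phase = rng.uniform(0.0, 2.0 * np.pi)
    shift = und.amplitude * np.sin(2.0 * np.pi * und.cycles * x / max(w, 1) + phase)
    tphase = rng.uniform(0.0, 2.0 * np.pi)
    tscale = 1.0 + und.thickness_amplitude * np.sin(
        2.0 * np.pi * und.cycles * 0.5 * x / max(w, 1) + tphase)

    dip = spec.foveal_dip
    center = w / 2.0 if dip.center is None else float(dip.center)
    depth = 0.05 * h if dip.depth is None else float(dip.depth)
    sigma = max(dip.width * w, 1e-6)
    dip_profile = depth * np.exp(-0.5 * ((x - center) / sigma) ** 2)

    thin = np.array([1.0 - _THINNING_SLOPES[k] * spec.severity
                     for k in SUBLAYER_IDS])

    boundaries = np.empty((6, w))
    boundaries[0] = depths[0] + shift
    for k in range(5):
        boundaries[k + 1] = boundaries[k] + base_thickness[k] * tscale * thin[k]
    boundaries += dip_profile[None, :] * np.asarray(_DIP_WEIGHTS)[:, None]

    if np.any(np.diff(boundaries, axis=0) <= 0):
        raise ValueError("spec produces unordered boundaries "
                         "(dip/undulation too strong for the layer geometry)")
    if boundaries.min() < 0 or boundaries.max() > h:
        raise ValueError("boundaries leave the image; reduce depths/amplitudes")
    return boundaries


def _labels_from_boundaries(boundaries: np.ndarray, height: int) -> np.ndarray:
    """Rasterize boundary curves to a sublayer label map.

    A pixel row ``r`` (center ``r + 0.5``) in column ``c`` gets class ``k``
    iff ``b_{k-1}[c] <= r + 0.5 < b_k[c]``; flat integer boundaries at
    distance ``t`` therefore yield exactly ``t`` rows per column.
    """

    w = boundaries.shape[1]
    centers = np.arange(height, dtype=float)[:, None] + 0.5
    labels = np.zeros((height, w), dtype=np.int64)
    for k in range(5):
        inside = (centers >= boundaries[k][None, :]) & \
                 (centers < boundaries[k + 1][None, :])
        labels[inside] = k + 1
    return labels


def _apply_noise(clean: np.ndarray, noise: Noise,
                 rng: np.random.Generator) -> np.ndarray:
    img = clean.copy()
    if noise.speckle_looks is not None and noise.speckle_looks > 0:
        looks = float(noise.speckle_looks)
        img = img * rng.gamma(shape=looks, scale=1.0 / looks, size=img.shape)
    if noise.gaussian_sigma > 0:
        img = img + rng.normal(0.0, noise.gaussian_sigma, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def render_bscan(boundaries: np.ndarray, spec: PhantomSpec
                 ) -> Tuple[np.ndarray, LabelMask, LabelMask]:
    """Render ``(image, sublayer mask, total-retina mask)`` from boundaries.

    The clean image is the per-class mean intensity (with severity-dependent
    ONL brightening); speckle and additive noise are then applied and the
    result clipped to [0, 1].  The total mask is the union of the five
    sublayers.
    """

    labels = _labels_from_boundaries(boundaries, spec.height)
    intensities = np.asarray(spec.layer_intensities, dtype=float).copy()
    intensities[2] = min(1.0, intensities[2] + _ONL_BRIGHTENING * spec.severity)
    clean = intensities[labels]
    image = _apply_noise(clean, spec.noise, _rng(spec.seed, 1))
    total = (labels > 0).astype(np.int64) * TOTAL_RETINA
    return image, LabelMask(labels, "sublayer"), LabelMask(total, "total")


def make_bscan(spec: PhantomSpec, lesion: Optional[LesionSpec] = None
               ) -> Tuple[np.ndarray, LabelMask, LabelMask, Optional[BoxAnnotation]]:
    """Convenience: boundaries -> render -> optional lesion injection."""

    boundaries = generate_boundaries(spec)
    image, sub, total = render_bscan(boundaries, spec)
    if lesion is None or not lesion.column_spans:
        return image, sub, total, None
    return inject_lesion(image, sub, total, lesion, spec)


def column_thicknesses(labels: np.ndarray) -> np.ndarray:
    """Per-column pixel thickness of each sublayer: ``(5, width)`` ints."""

    return np.stack([(labels == k).sum(axis=0) for k in SUBLAYER_IDS])


def inject_lesion(image: np.ndarray, sublayer: LabelMask, total: LabelMask,
                  lesion: LesionSpec, spec: PhantomSpec
                  ) -> Tuple[np.ndarray, LabelMask, LabelMask, Optional[BoxAnnotation]]:
    """Collapse the lesion's absent layers inside its column spans.

    Inside each span the listed layers' thickness shrinks by
    ``lesion.severity`` (to zero at severity 1); the column is rebuilt from
    the band top so the total retina stays one connected (thinner) band, and
    hyper-reflective debris plus fresh noise are painted into the band.

    The ground-truth box is a single orthogonal box covering *all* columns
    in which at least one sublayer ended with zero thickness, merged across
    disjoint spans; its rows span the retina band over those columns.
    Severity 0 returns the inputs unchanged with no box.
    """

    if sublayer.mode != "sublayer" or total.mode != "total":
        raise ValueError("inject_lesion expects sublayer + total masks")
    h, w = sublayer.shape
    for start, end in lesion.column_spans:
        if end > w:
            raise ValueError(f"span [{start}, {end}) exceeds width {w}")
    if lesion.severity == 0.0:
        return image, sublayer, total, None

    labels = sublayer.labels.copy()
    img = image.copy()
    absent = lesion.absent_ids()
    rng = _rng(spec.seed, 2)
    intensities = np.asarray(spec.layer_intensities, dtype=float).copy()
    intensities[2] = min(1.0, intensities[2] + _ONL_BRIGHTENING * spec.severity)

    in_span = np.zeros(w, dtype=bool)
    for start, end in lesion.column_spans:
        in_span[start:end] = True

    for c in np.flatnonzero(in_span):
        col = labels[:, c]
        band = np.flatnonzero(col > 0)
        if band.size == 0:
            continue
        top = band[0]
        t = np.array([(col == k).sum() for k in SUBLAYER_IDS])
        new_t = t.copy()
        for k in absent:
            new_t[k - 1] = int(round(t[k - 1] * (1.0 - lesion.severity)))
        # rebuild the column: contiguous runs 1..5 from the same band top
        col[:] = 0
        r = top
        for k in SUBLAYER_IDS:
            col[r:r + new_t[k - 1]] = k
            r += new_t[k - 1]
        labels[:, c] = col
        # repaint the column image: class intensities + debris + noise
        clean = intensities[col]
        band_rows = np.flatnonzero(col > 0)
        if band_rows.size:
            debris = rng.random(band_rows.size) < lesion.debris_density
            clean[band_rows[debris]] = lesion.debris_intensity
        img[:, c] = _apply_noise(clean, spec.noise, rng)

    thick = column_thicknesses(labels)
    affected = np.flatnonzero((thick == 0).any(axis=0))
    box: Optional[BoxAnnotation] = None
    if affected.size:
        x0, x1 = int(affected[0]), int(affected[-1]) + 1
        band_any = labels[:, x0:x1] > 0
        rows = np.flatnonzero(band_any.any(axis=1))
        if rows.size == 0:  # fully collapsed band: fall back to prior extent
            rows = np.flatnonzero((total.labels[:, x0:x1] > 0).any(axis=1))
        y0, y1 = int(rows[0]), int(rows[-1]) + 1
        box = BoxAnnotation(x0, x1, y0, y1)

    new_total = (labels > 0).astype(np.int64) * TOTAL_RETINA
    return img, LabelMask(labels, "sublayer"), LabelMask(new_total, "total"), box


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """A multi-site longitudinal cohort of phantom OCT volumes.

    One volume is produced per (patient, visit, eye) with
    ``slices_per_volume`` B-scans.  Diseased patients draw a baseline
    severity and a per-visit progression slope, so severity increases
    monotonically across visits; severity is highest for central slices
    (macular damage).  ``diseased=False`` makes every scan severity 0.
    """

    sites: Mapping[str, int] = field(
        default_factory=lambda: {"site1": 4, "site2": 3})
    visits: int = 5
    eyes: Tuple[str, ...] = ("OD", "OS")
    slices_per_volume: int = 49
    diseased: bool = True
    baseline_severity: Tuple[float, float] = (0.15, 0.60)
    progression_rate: Tuple[float, float] = (0.02, 0.10)
    lesion_onset: float = 0.45
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    seed: int = 0


def _slice_modulation(n_slices: int) -> np.ndarray:
    """Severity weight per slice: 1 at the volume center, ~0.6 at the rim."""

    s = np.arange(n_slices, dtype=float)
    c = (n_slices - 1) / 2.0
    g = np.exp(-0.5 * ((s - c) / max(0.35 * n_slices, 1e-6)) ** 2)
    return 0.6 + 0.4 * g


def plan_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Build the cohort manifest without rendering any pixels.

    Returns one row per B-scan with columns ``patient_id, site_id, eye,
    visit, slice_index, severity, scan_seed``.  Identical seeds give
    bit-identical manifests.
    """

    rng = _rng(spec.seed, 10)
    mod = _slice_modulation(spec.slices_per_volume)
    rows: List[dict] = []
    for site_id in spec.sites:
        n_patients = spec.sites[site_id]
        for p in range(n_patients):
            patient_id = f"{site_id}-P{p:04d}"
            if spec.diseased:
                base = rng.uniform(*spec.baseline_severity)
                slope = rng.uniform(*spec.progression_rate)
            else:
                base = slope = 0.0
            for visit in range(spec.visits):
                sev_visit = min(1.0, base + slope * visit)
                for eye in spec.eyes:
                    for s in range(spec.slices_per_volume):
                        rows.append({
                            "patient_id": patient_id,
                            "site_id": site_id,
                            "eye": eye,
                            "visit": visit,
                            "slice_index": s,
                            "severity": round(float(sev_visit * mod[s]), 6),
                            "scan_seed": int(rng.integers(0, 2**31 - 1)),
                        })
    return pd.DataFrame(rows)


def lesion_for_severity(severity: float, width: int, onset: float,
                        rng: np.random.Generator) -> Optional[LesionSpec]:
    """Derive a focal lesion from scan severity (None below onset).

    Lesion width grows with severity beyond onset; spans sit near the
    fovea with jitter; the photoreceptor layers always collapse, joined by
    ONL and RPE at high severity.  Collapse severity is 1 (a true box).
    """

    if severity <= onset:
        return None
    frac = min(0.5, 0.15 + 0.9 * (severity - onset))
    span_w = max(8, int(round(frac * width)))
    center = int(rng.normal(width / 2.0, 0.08 * width))
    start = int(np.clip(center - span_w // 2, 0, max(width - span_w, 0)))
    spans: List[Tuple[int, int]] = [(start, start + span_w)]
    if severity > onset + 0.25 and rng.random() < 0.5:
        w2 = max(8, span_w // 3)
        if start >= w2 + 4:
            spans.insert(0, (max(0, start - w2 - 4), start - 4))
        elif start + span_w + 4 + w2 <= width:
            spans.append((start + span_w + 4, start + span_w + 4 + w2))
    layers: List[str] = ["PR-IS", "PR-OS"]
    if severity > onset + 0.15:
        layers.append("ONL")
    if severity > onset + 0.35:
        layers.append("RPE")
    return LesionSpec(column_spans=tuple(spans), absent_layers=tuple(layers),
                      severity=1.0)


def realize_scan(row: Mapping, spec: CohortSpec
                 ) -> Tuple[np.ndarray, LabelMask, LabelMask, Optional[BoxAnnotation]]:
    """Render one manifest row into image + masks + optional box."""

    severity = float(row["severity"])
    scan_seed = int(row["scan_seed"])
    pspec = replace(spec.phantom, severity=severity, seed=scan_seed)
    rng = _rng(scan_seed, 3)
    lesion = lesion_for_severity(severity, pspec.width, spec.lesion_onset, rng)
    return make_bscan(pspec, lesion)


def generate_cohort(spec: CohortSpec, outdir: Path) -> pd.DataFrame:
    """Render the whole cohort to ``outdir`` and return the manifest.

    Writes per-scan grayscale PNGs and indexed-PNG label masks, a COCO-style
    ``boxes.json``, and ``manifest.csv`` with one row per B-scan including
    relative file paths.  Intended for small cohorts; use ``plan_cohort``
    for bookkeeping at scale.
    """

    from . import io as paio

    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(parents=True, exist_ok=True)
    manifest = plan_cohort(spec)
    boxes: Dict[str, Optional[BoxAnnotation]] = {}
    img_paths, sub_paths, tot_paths = [], [], []
    for _, row in manifest.iterrows():
        stem = (f"{row.patient_id}_v{row.visit}_{row.eye}"
                f"_s{int(row.slice_index):03d}")
        image, sub, total, box = realize_scan(row, spec)
        ip = f"images/{stem}.png"
        sp = f"masks/{stem}_sublayer.png"
        tp = f"masks/{stem}_total.png"
        paio.save_image(outdir / ip, image)
        paio.save_mask(outdir / sp, sub)
        paio.save_mask(outdir / tp, total)
        boxes[stem] = box
        img_paths.append(ip)
        sub_paths.append(sp)
        tot_paths.append(tp)
    manifest = manifest.assign(image_path=img_paths,
                               sublayer_mask_path=sub_paths,
                               total_mask_path=tot_paths,
                               scan_id=[f"{r.patient_id}_v{r.visit}_{r.eye}"
                                        f"_s{int(r.slice_index):03d}"
                                        for r in manifest.itertuples()])
    paio.save_coco_boxes(outdir / "boxes.json", boxes,
                         (spec.phantom.height, spec.phantom.width))
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest
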