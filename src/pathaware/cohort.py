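"""Site-stratified patient splitting and central/peripheral B-scan sampling.

The study design this reproduces: patients enrolled at multiple sites are
randomly assigned to train/validation/test in an 8:1:1 ratio *within each
site*, with no patient in more than one set.  Each 49-slice macular volume
is divided into the middle 11 "central" slices and the remaining 38
"peripheral" ones; per patient a fixed number of B-scans is drawn — 30%
central / 70% peripheral, pooled across all visits and both eyes — 3 per
training patient (the initial annotated set) and 16 per validation/test
patient (fixed for the whole study).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

SPLITS = ("train", "validation", "test")


@dataclass
class SplitAssignment:
    """Per-patient set membership plus per-site bookkeeping."""

    assignment: Dict[str, str]                  # patient_id -> split
    per_site_counts: Dict[str, Dict[str, int]]  # site -> split -> count

    def patients(self, split: str) -> List[str]:
        return sorted(p for p, s in self.assignment.items() if s == split)

    def counts(self) -> Dict[str, int]:
        out = {s: 0 for s in SPLITS}
        for s in self.assignment.values():
            out[s] += 1
        return out

    def validate_partition(self, all_patients: Iterable[str]) -> None:
        missing = set(all_patients) - set(self.assignment)
        if missing:
            raise ValueError(f"patients without a split: {sorted(missing)[:5]}")


@dataclass(frozen=True)
class SamplingPlan:
    """How many B-scans to draw per patient and the central share."""

    n_per_patient: int
    central_fraction: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_patient < 0:
            raise ValueError("n_per_patient must be >= 0")
        if not 0.0 <= self.central_fraction <= 1.0:
            raise ValueError("central_fraction must lie in [0, 1]")


def round_half_up(x: float) -> int:
    """Round with ties away from zero toward +inf (0.5 -> 1, 4.8 -> 5)."""

    return int(math.floor(x + 0.5))


def split_patients_by_site(patient_sites: Mapping[str, str],
                           ratio: Tuple[int, int, int] = (8, 1, 1),
                           seed: int = 0) -> SplitAssignment:
    """Randomly assign patients to train/validation/test within each site.

    Rounding rule: validation and test each get ``floor(n * share)``
    patients, with a minimum of 1 whenever the site has at least 3
    patients; the remainder trains.  Sites with fewer than 3 patients go
    entirely to training (with a warning).  Deterministic given ``seed``.
    """

    total = sum(ratio)
    val_share, test_share = ratio[1] / total, ratio[2] / total
    rng = np.random.default_rng(seed)
    assignment: Dict[str, str] = {}
    per_site: Dict[str, Dict[str, int]] = {}

    by_site: Dict[str, List[str]] = {}
    for patient, site in patient_sites.items():
        by_site.setdefault(site, []).append(patient)

    for site in sorted(by_site):
        patients = sorted(by_site[site])
        n = len(patients)
        order = rng.permutation(n)
        shuffled = [patients[i] for i in order]
        if n < 3:
            warnings.warn(f"site {site!r} has {n} patients (<3): all to train")
            n_val = n_test = 0
        else:
            n_val = max(1, math.floor(n * val_share))
            n_test = max(1, math.floor(n * test_share))
        counts = {"validation": n_val, "test": n_test,
                  "train": n - n_val - n_test}
        per_site[site] = counts
        for p in shuffled[:n_val]:
            assignment[p] = "validation"
        for p in shuffled[n_val:n_val + n_test]:
            assignment[p] = "test"
        for p in shuffled[n_val + n_test:]:
            assignment[p] = "train"
    return SplitAssignment(assignment, per_site)


def group_bscans(n_slices: int, central_count: int = 11
                 ) -> Tuple[np.ndarray, np.ndarray]:
    """Split slice indices of one volume into (central, peripheral).

    Central = the middle ``central_count`` slices, using a floor offset
    ``(n - central_count) // 2`` for even remainders; a 49-slice volume
    yields central indices 19..29.  Volumes smaller than ``central_count``
    are all central (with a warning).
    """

    if n_slices < central_count:
        warnings.warn(f"volume of {n_slices} slices < {central_count}: "
                      "treating all slices as central")
        return np.arange(n_slices), np.arange(0)
    offset = (n_slices - central_count) // 2
    central = np.arange(offset, offset + central_count)
    peripheral = np.setdiff1d(np.arange(n_slices), central)
    return central, peripheral


def classify_central(manifest: pd.DataFrame, n_slices: int = 49,
                     central_count: int = 11) -> pd.Series:
    """Boolean Series: True where the row's slice_index is central."""

    central, _ = group_bscans(n_slices, central_count)
    return manifest["slice_index"].isin(central)


def sample_bscans(central_pool: pd.DataFrame, peripheral_pool: pd.DataFrame,
                  plan: SamplingPlan,
                  rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Draw one patient's sample: round(n*fraction) central, rest peripheral.

    Half-up rounding on the central allocation (16 -> 5 central + 11
    peripheral, 3 -> 1 + 2).  Sampling is without replacement; a pool
    smaller than its request yields everything available with a warning.
    """

    if rng is None:
        rng = np.random.default_rng(plan.seed)
    n = plan.n_per_patient
    if n == 0:
        return central_pool.iloc[:0]
    n_central = round_half_up(n * plan.central_fraction)
    n_peripheral = n - n_central

    def draw(pool: pd.DataFrame, k: int, kind: str) -> pd.DataFrame:
        if len(pool) < k:
            warnings.warn(f"{kind} pool has {len(pool)} < {k} B-scans: "
                          "taking all")
            k = len(pool)
        idx = rng.choice(len(pool), size=k, replace=False)
        return pool.iloc[np.sort(idx)]

    return pd.concat([draw(central_pool, n_central, "central"),
                      draw(peripheral_pool, n_peripheral, "peripheral")],
                     ignore_index=True)


def build_initial_sets(manifest: pd.DataFrame, split: SplitAssignment,
                       train_plan: SamplingPlan = SamplingPlan(3),
                       eval_plan: SamplingPlan = SamplingPlan(16),
                       n_slices: int = 49, seed: int = 0
                       ) -> Dict[str, pd.DataFrame]:
    """Build initial train/validation/test manifests plus the unannotated pool.

    Per patient, scans across all visits and both eyes are pooled, grouped
    central/peripheral, shuffled and sampled per the plan (3 for training
    patients, 16 for validation/test).  The pool is every remaining B-scan
    of the training patients — the reservoir the iterative loop draws from.
    """

    split.validate_partition(manifest["patient_id"].unique())
    is_central = classify_central(manifest, n_slices)
    rng = np.random.default_rng(seed)
    out: Dict[str, List[pd.DataFrame]] = {s: [] for s in SPLITS}
    pool: List[pd.DataFrame] = []

    for patient, rows in manifest.groupby("patient_id", sort=True):
        which = split.assignment[patient]
        plan = train_plan if which == "train" else eval_plan
        cen = rows[is_central.loc[rows.index]]
        per = rows[~is_central.loc[rows.index]]
        sampled = sample_bscans(cen, per, plan, rng)
        out[which].append(sampled)
        if which == "train":
            key_cols = ["patient_id", "eye", "visit", "slice_index"]
            taken = set(map(tuple, sampled[key_cols].itertuples(index=False)))
            rest = rows[~rows[key_cols].apply(tuple, axis=1).isin(taken)]
            pool.append(rest)

    def cat(frames: List[pd.DataFrame]) -> pd.DataFrame:
        if not frames:
            return manifest.iloc[:0]
        return pd.concat(frames, ignore_index=True)

    result = {s: cat(out[s]) for s in SPLITS}
    result["pool"] = cat(pool)
    return result


def assert_no_patient_leakage(manifests: Mapping[str, pd.DataFrame]) -> None:
    """Raise if any patient occurs in more than one of train/val/test."""

    seen: Dict[str, str] = {}
    for name in SPLITS:
        if name not in manifests:
            continue
        for p in manifests[name]["patient_id"].unique():
            if p in seen and seen[p] != name:
                raise AssertionError(
                    f"patient {p} appears in both {seen[p]} and {name}")
            seen[p] = name
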