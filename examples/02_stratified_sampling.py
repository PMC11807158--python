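"""Cohort bookkeeping: site-stratified split and 30/70 B-scan sampling.

Builds a 259-patient, 9-site longitudinal manifest (5 visits, both eyes,
49 B-scans per volume), splits patients 8:1:1 within each site, and draws
the initial annotated sets: 3 B-scans per training patient, 16 per
validation/test patient, 30% central / 70% peripheral.
"""

from pathaware import CohortSpec, SamplingPlan, plan_cohort
from pathaware.cohort import build_initial_sets, split_patients_by_site
from pathaware.study import BOOKKEEPING_SITES

spec = CohortSpec(sites=BOOKKEEPING_SITES, visits=5, eyes=("OD", "OS"),
                  slices_per_volume=49, seed=0)
manifest = plan_cohort(spec)
print(f"patients: {manifest['patient_id'].nunique()}, "
      f"volumes: {manifest.groupby(['patient_id', 'visit', 'eye']).ngroups}, "
      f"B-scans: {len(manifest)}")

sites = dict(manifest.groupby("patient_id")["site_id"].first())
split = split_patients_by_site(sites, ratio=(8, 1, 1), seed=0)
print("patient split:", split.counts())

sets = build_initial_sets(manifest, split, train_plan=SamplingPlan(3),
                          eval_plan=SamplingPlan(16), n_slices=49, seed=0)
for name in ("train", "validation", "test", "pool"):
    print(f"{name:>10}: {len(sets[name]):7d} B-scans")
print("The pool is the unannotated reservoir the iterative loop samples "
      "200 scans from per loop.")
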