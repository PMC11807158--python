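"""The full three-stage pipeline: detect the box, segment, compose.

Uses the models from the training comparison, runs box detection and the
composed prediction on the diseased test set, and prints detection AP and
the final segmentation report.
"""

import numpy as np

from pathaware import RuleBasedDetector, TrainConfig, run_pipeline, \
    train_total_retina
from pathaware import study

exp = study.run_directional_experiment(seed=7)
images, subs, totals, boxes = exp["test_diseased"]

# dedicated total-retina model (2 classes), trained on a few extra scans
hi, _, ht, _ = study.build_scan_set(False, 20, 901)
di, _, dt, _ = study.build_scan_set(True, 20, 902)
total_model, _ = train_total_retina(hi + di, ht + dt, hi[:4], ht[:4],
                                    TrainConfig(epochs=8, seed=0))

detector = RuleBasedDetector(segmenter=exp["pa_model"])
report = run_pipeline(images, totals, subs, boxes, detector, total_model,
                      exp["pa_model"])

print(f"detection: AP50={report.detection.ap50:.1f}  "
      f"AP75={report.detection.ap75:.1f}  mAP={report.detection.map:.1f}")
print(f"total retina Dice: "
      f"{report.total.summary.loc['Total retina', 'mean']:.4f}")
print("sublayer Dice outside ground-truth boxes (mean +/- sd):")
print(report.sublayer.summary.round(3).to_string())
comp = report.composed[0].labels
print(f"\ncomposed output classes in scan 0: "
      f"{sorted(int(v) for v in np.unique(comp))} "
      "(6 = total retina inside the detected box)")
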