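"""Redundancy reduction, R-squared selection, and harmonized splits.

Shows the preprocessing chain for one cohort: cluster Spearman-redundant
features and keep the highest-variance survivor, build the ten
patient-grouped balanced folds, and select 8 features on one fold's
training rows.
"""

import numpy as np

from petqml import make_three_cohort_suite, make_cv_scheme, spearman_redundancy_reduce
from petqml.prep import r2_rank_select

prostate = make_three_cohort_suite(seed=1)[0]
print(f"cohort: {len(prostate)} lesions x {len(prostate.feature_names)} features")

for srt in (0.7, 0.8, 0.9):
    reduced, report = spearman_redundancy_reduce(prostate, srt)
    print(f"SRT {srt}: {len(report.survivors)} survivors, "
          f"{len(report.dropped)} dropped in {sum(len(c) > 1 for c in report.clusters)} clusters")
# Higher thresholds treat fewer features as redundant, so more survive.

scheme = make_cv_scheme(prostate, seed=1, cohort_id="prostate")
fold = scheme.folds[0]
labels = dict(zip(prostate.sample_ids, prostate.labels))
test_y = [labels[s] for s in fold.test_ids]
print(f"\nfold 1: {len(fold.train_ids)} train / {len(fold.test_ids)} test lesions, "
      f"test positives {sum(test_y)} = negatives {len(test_y) - sum(test_y)}")

reduced, _ = spearman_redundancy_reduce(prostate, 0.7)
train = reduced.subset(fold.train_ids)
selected = r2_rank_select(train, 8)
print(f"top-8 features by train-set R^2: {selected}")
# Selection uses the training rows only, so every fold can pick a
# different panel without leaking test information.
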