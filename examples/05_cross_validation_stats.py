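"""Fold assignment and paired statistical comparison of two conditions.

Twenty-four patients are dealt into four folds (as in a four-fold
cross-validation of a segmentation model), and per-patient DSC values from
two hypothetical models are compared: Shapiro–Wilk checks that the paired
differences are compatible with normality, then the paired t-test asks
whether the mean difference is zero.
"""

import numpy as np

from aortamorph import make_cv_layout, paired_comparison

patients = [f"P{i:02d}" for i in range(1, 25)]
layout = make_cv_layout(patients, k=4, seed=7)
for i, fold in enumerate(layout.folds()):
    print(f"fold {i}: {' '.join(fold)}")

rng = np.random.default_rng(7)
dsc_model_a = rng.normal(0.88, 0.04, 24).clip(0, 1)
dsc_model_b = (dsc_model_a - rng.normal(0.015, 0.02, 24)).clip(0, 1)

cmp = paired_comparison(dsc_model_a, dsc_model_b, metric_name="dsc")
print(f"\nShapiro-Wilk on differences: W = {cmp.shapiro_w:.4f}, "
      f"p = {cmp.shapiro_p:.4f} (normality {'not rejected' if cmp.normal else 'rejected'})")
print(f"paired t-test: t = {cmp.t_statistic:.3f}, p = {cmp.t_p:.4f} "
      f"-> {'significant' if cmp.significant else 'not significant'} at alpha = 0.05")
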