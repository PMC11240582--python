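"""Run the full pipeline on a small simulated patient cohort.

One call generates seeded phantoms with degraded predictions, evaluates the
six metrics per patient, extracts flaps, quantifies morphometry for ground
truth and prediction, writes CSV reports plus NIfTI volumes and STL meshes,
and returns a machine-readable summary.
"""

import json

from aortamorph import RunConfig, run_pipeline

config = RunConfig(
    mode="full",
    out_dir="runs/example_cohort",
    seed=42,
    n_patients=3,
    phantom={"n_slices": 8, "grid_shape": [96, 96]},
    degradation={"boundary_shift_mm": 0.9, "flip_fraction": 0.03},
)
summary = run_pipeline(config)
print(json.dumps(summary, indent=2, default=str))
print(
    "\nmean_dsc_* summarise segmentation overlap across the cohort;"
    "\nre_*_pct are mean per-patient relative errors of predicted vs"
    "\nground-truth morphometry, the headline quantification accuracy."
)
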