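"""Evaluate a degraded prediction against ground truth with the six metrics.

A controlled degradation (random boundary dilation/erosion plus label swaps
on boundary voxels) stands in for an imperfect automatic segmentation.  The
six metrics — accuracy, precision, recall, IoU, DSC (all per-voxel over the
whole volume) and the Hausdorff distance in mm — quantify how far the
prediction departs from the annotation.
"""

from aortamorph import (
    DegradationSpec,
    PhantomSpec,
    degrade_prediction,
    generate_phantom,
    patient_metrics,
)

result = generate_phantom(PhantomSpec(n_slices=20, seed=3))
pred = degrade_prediction(
    result.annotation,
    DegradationSpec(boundary_shift_mm=0.9, flip_fraction=0.03, seed=3),
)

metrics = patient_metrics(result.annotation, pred)
names = {1: "TL", 2: "FL"}
header = f"{'label':>5} {'acc%':>7} {'prec%':>7} {'rec%':>7} {'IoU%':>7} {'DSC%':>7} {'HD mm':>7}"
print(header)
for label, m in metrics.items():
    print(
        f"{names[label]:>5} {100 * m.accuracy:7.2f} {100 * m.precision:7.2f} "
        f"{100 * m.recall:7.2f} {100 * m.iou:7.2f} {100 * m.dsc:7.2f} {m.hd:7.2f}"
    )
print(
    "\nDSC near 100% means near-perfect voxel overlap; the HD is driven by"
    "\nthe single worst-placed voxel, so boundary label swaps dominate it."
)
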