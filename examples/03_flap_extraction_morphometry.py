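"""Recover the intimal flap from a TL/FL annotation and quantify morphology.

The annotation labels only the two lumens; the flap is rediscovered per
slice by evolving an active contour over the merged TL+FL region (bridging
the unlabelled gap) and subtracting the lumens.  Recovered per-patient
morphometry is then compared with the phantom's closed-form truth.
"""

import numpy as np

from aortamorph import PhantomSpec, extract_flap_volume, generate_phantom
from aortamorph.flap import SliceRegions
from aortamorph.morphometry import patient_morphometry, slice_morphometry

spec = PhantomSpec(n_slices=12, grid_shape=(96, 96), seed=21)
result = generate_phantom(spec)

flap_vol = extract_flap_volume(result.annotation)
recovered = flap_vol.voxels == 3
true_band = result.full_truth.voxels == 3
dsc = 2 * (recovered & true_band).sum() / (recovered.sum() + true_band.sum())
print(f"flap recovery DSC vs analytic band: {dsc:.3f}")

slices = []
for z in range(flap_vol.n_slices):
    sl = flap_vol.voxels[z]
    regions = SliceRegions(
        tl_mask=sl == 1, fl_mask=sl == 2, flap_mask=sl == 3,
        aorta_mask=sl > 0, in_plane_spacing=flap_vol.in_plane_spacing,
    )
    slices.append(slice_morphometry(regions, z))
patient = patient_morphometry(slices, patient_id="phantom")

truth = result.truth
rows = [
    ("aortic diameter (mm)", patient.aortic_diameter, truth.aortic_diameter),
    ("TL area (mm^2)", patient.tl_area, truth.tl_area),
    ("FL area (mm^2)", patient.fl_area, truth.fl_area),
    ("flap thickness (mm)", patient.flap_thickness, truth.flap_thickness),
]
print(f"\n{'quantity':<22} {'recovered':>10} {'truth':>10} {'err':>8}")
for name, got, want in rows:
    print(f"{name:<22} {got:10.2f} {want:10.2f} {got - want:+8.2f}")
print(
    "\nErrors of a fraction of a pixel (0.82 mm in-plane) show the"
    "\nmeasurement chain, not the segmentation, limits the accuracy."
)
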