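# Methods

## Problem setting

A dissected aorta presents on contrast CT as two blood-filled channels — the
true lumen (TL) and false lumen (FL) — separated by the thin intimal flap.
Segmentation pipelines typically deliver TL/FL label volumes in which the
flap is *not* labelled: annotators trace the two lumens and leave the
membrane between them as background. Everything downstream of such a label
volume is in scope here: recovering the flap, measuring the vessel, scoring
a predicted segmentation against a reference, and comparing two segmenters
statistically. Everything upstream (the segmenter itself, DICOM handling,
intensity preprocessing) is out of scope.

All volumes are 3D integer grids in (z, y, x) order with physical voxel
spacing in mm; labels are 0 = background, 1 = TL, 2 = FL, 3 = flap (present
only after extraction). A configurable remap table translates foreign label
schemes at read time.

## Flap recovery

Per slice, the procedure is:

1. **Whole-aorta delineation.** The merged TL ∪ FL mask is evolved with a
   morphological Chan–Vese active contour (curvature-regularised,
   region-homogeneity-driven). To let the contour bridge the unlabelled gap
   between the lumens, the binary image is first Gaussian-smoothed with
   σ equal to the closing radius, so gap pixels flanked by foreground on
   both sides acquire intermediate intensity and are captured by the region
   term; the level set is initialised from the morphological closing of the
   union. The converged region is hole-filled, opened by one pixel (removing
   any sub-pixel rim of over-segmentation that would otherwise survive
   subtraction as a spurious ring), constrained to be a superset of TL ∪ FL,
   and restricted to components that touch the lumens.
2. **Subtraction.** flap = aorta ∖ TL ∖ FL.
3. **Adjacency filtering.** Residual components not 8-adjacent to *both*
   lumens are contour artifacts, not flap, and are discarded (switchable via
   `adjacency_required`).

The returned regions satisfy aorta = TL ⊔ FL ⊔ flap exactly, and re-running
the extraction on its own output reproduces it (label 3 is ignored on
input). Slices missing either lumen are skipped and logged — the per-slice
analogue of excluding patients whose ascending-aorta tear is too small to
present all three regions.

A pure morphological-closing engine (`engine="closing"`) is kept alongside
the active contour: it separates the geometric idea (region subtraction
inside a bridged hull) from the contour-evolution machinery and serves as a
debugging cross-check. On phantom data the two engines agree to within the
rim pixel.

### Contour parameters

| parameter | default | meaning |
|---|---|---|
| `init_dilation_mm` | 3.0 mm | closing radius for the initial region; must exceed half the widest expected flap for the gap to be bridged |
| `max_iterations` | 60 | Chan–Vese evolution steps per slice |
| `smoothing_passes` | 1 | curvature-smoothing sweeps per step |
| `convergence_window` | 5 | recurrence of the level set within this window counts as converged (morphological snakes commonly settle into short limit cycles); non-recurrence logs a warning and returns the last contour |
| `adjacency_required` | true | drop residual components not touching both lumens |

## Evaluation metrics

Accuracy, precision, recall, IoU and DSC are computed from per-voxel
confusion counts over the gathered 3D volume (not averaged over per-slice
values). Undefined ratios (zero denominators, e.g. an empty prediction) are
reported as NaN with a warning and excluded pairwise from statistics —
coercing them to 0 would silently bias patient averages.

The Hausdorff distance is taken between the *full* voxel-centre point sets
of a label in physical mm (index × spacing), via one exact Euclidean
distance transform per direction sampled on the opposite set. Boundary-only
formulations are inequivalent when one set has an interior cavity, so they
are deliberately not used. If the label is missing from either volume the
distance to the empty set is undefined; +inf is returned with a warning.
Reported HD units are mm by default; `hd_units="voxel"` reports index-space
distances instead, since published HD tables often omit units.

Patients are dealt into k equal-as-possible folds by seeded shuffle +
round-robin. Paired comparisons compute d = a − b per patient, Shapiro–Wilk
W and p on d, and the two-sided paired t statistic mean(d)/(sd(d)/√n) on
n − 1 df (via `scipy.stats`; cross-checked against an independent reference
implementation to 1e-10 in the tests). Identical pairs raise a
zero-variance error rather than emitting an undefined t.

## Morphometry

- **Maximum diameter** is the maximum Feret diameter: the largest pairwise
  distance between foreground pixel centres, computed exactly over convex
  hull vertices. This is the only reading under which a crescent-shaped FL
  can have a diameter approaching the whole-aorta diameter, as observed in
  dissected aortas; equivalent-circle diameters behave differently.
- **Areas** are pixel count × pixel area.
- **Flap thickness** is the mean local width of the band: for a uniform
  ribbon of width w, the distance-to-boundary averaged over the ribbon is
  exactly w/4, so thickness = 4 × mean EDT over the region footprint. The
  mask is upsampled 4× and closed by half a pixel first (de-jagging the
  rasterised boundary), and the residual half-subpixel centre-to-centre
  offset is subtracted analytically. Skeleton-sampled estimators were
  evaluated and rejected: on bands 2–4 px wide the medial axis is dominated
  by quantisation branches and under-reads width by up to a pixel. An
  independent area/skeleton-length estimator is kept as a cross-check.
  The estimator assumes elongated geometry and under-reads blobs; a region
  at single-pixel width degenerates to one pixel spacing with a warning.
- **Patient values** are unweighted means over slices containing all three
  regions, optionally restricted to a configured z-interval per patient
  (standing in for the manually chosen ascending-aorta section; no
  automatic anatomical landmarking is attempted). A patient with no passing
  slice is excluded with a logged reason.
- **Relative error** is |pred − gt|/gt computed per patient and then
  averaged. Averaging first and taking the relative error of the means
  would let signed errors cancel and understate the true per-patient
  discrepancy.

Diameters and areas are in-plane only (no 3D obliquity correction), matching
per-CT-slice measurement practice.

## Phantom generator

Each slice is a filled disc (outer wall thickness zero: aorta = TL ∪ flap ∪
FL) cut by a straight chord band of width `flap_thickness` at perpendicular
offset `flap_offset` and orientation `flap_angle`; the smaller circular
segment is TL, matching the usual asymmetry where the FL outgrows the TL.
The tube centre drifts sinusoidally in-plane along z (default amplitude
5 mm) so per-slice machinery is exercised by genuinely varying slices.
Defaults: 50 mm outer diameter, 2.4 mm flap, 10 mm offset, spacing
1.25 × 0.8242 × 0.8242 mm — representative of a resampled contrast-CT
dissection study. Voxels are assigned by pixel-centre inclusion.

Two volumes are produced: an *annotation-style* ground truth with the band
left as background (what an expert annotation of the lumens looks like, and
what flap extraction must start from) and a *full truth* with the band
labelled 3 (the oracle for flap-recovery tests). All truth quantities —
diameters, circular-segment areas R²·arccos(a/R) − a·√(R² − a²), flap
thickness — are closed-form.

The degradation model applies, per slice and label, a random morphological
dilation or erosion with radius up to `boundary_shift_mm` (default 0.9 mm),
swaps `flip_fraction` (default 3%) of TL/FL boundary voxels between the two
lumen labels, and zeroes `dropout_slices` random slices. All randomness
flows from explicit seeds through named generators; identical specs yield
identical volumes.

**What the phantom does not emulate:** curved or spiralling flaps (the
chord-band is a deliberate geometric simplification), branch vessels and the
arch, false-lumen thrombus, partial-volume intensity effects, and
anatomically correlated segmentation errors. Passing the phantom suite
therefore demonstrates that the *measurement* chain is correct and
well-conditioned at clinical voxel sizes — not that any particular segmenter
performs well on real CT.

## Problem sizes and tolerances

The validation suite uses 96×96 slices (≈79 mm field of view) with 8–12
slices per phantom and a 10-phantom sweep spanning 35–55 mm outer diameter,
1.5–3.5 mm flap thickness and 0–12 mm offset; the acceptance script runs an
8-patient cohort with 12 slices each plus a 2000-replicate null calibration
of the paired t-test (n = 24 pairs). Documented recovery tolerances: aortic
diameter within one in-plane pixel diagonal, lumen areas within 3% of the
analytic values, flap thickness within one in-plane pixel, per-slice flap
DSC ≥ 0.80. Measured performance is comfortably inside these bounds (flap
DSC ≥ 0.94 across the sweep).

Meshes are 0.5-level marching-cubes isosurfaces of the padded binary label
mask, vertices in mm, exported per label as STL/PLY; optional Laplacian
smoothing is off by default because it shrinks enclosed volume. The
single-voxel isosurface is an octahedron enclosing ~1/6 of the voxel volume
— volume fidelity (±5%) holds for multi-voxel structures, which the tests
check on a tube phantom.

## Known limitations

- The active-contour stage has no notion of anatomy; gross under-closing can
  occur if `init_dilation_mm` is far below half the flap width, and the
  closing-radius default bounds the widest bridgeable gap (~6 mm).
- Thickness estimation assumes ribbon geometry; on nearly circular residual
  regions it is biased low.
- Feret diameters on very sparse masks (a handful of noise voxels) are
  dominated by outliers — which is also why boundary label swaps inflate the
  Hausdorff distance; both behave as designed but warrant inspection of the
  per-slice CSVs when predictions are noisy.
- Patient-level slice selection is configuration (a z-interval), not
  automatic landmark detection.
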