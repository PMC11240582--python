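"""Synthetic dissected-aorta phantoms with analytically known morphometry.

Each phantom slice is a filled disc (the aortic cross-section, outer wall
thickness zero) partitioned by a straight chord band of configurable width —
the intimal flap — into two lumens.  By convention the smaller circular
segment is the true lumen (TL) and the larger the false lumen (FL), matching
the typical asymmetry of dissected aortas.  The tube centre can drift
sinusoidally in-plane along z to exercise per-slice machinery.

Two ground-truth flavours are produced:

* ``annotation`` — the flap band is left as background (label 0), emulating a
  manual TL/FL annotation in which the flap is *not* labelled and must be
  rediscovered downstream;
* ``full_truth`` — the flap band carries label 3, serving as the oracle for
  flap-extraction tests.

All geometric truth values (diameters, circular-segment areas, flap
thickness) follow in closed form from the spec parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import dilation, disk, erosion

from .errors import ValidationError
from .volume_io import BACKGROUND, FALSE_LUMEN, FLAP, LabelVolume, TRUE_LUMEN

DEFAULT_SPACING = (1.25, 0.8242, 0.8242)  # (z, y, x) mm, contrast-CT protocol


@dataclass(frozen=True)
class PhantomSpec:
    """Analytic geometry of a synthetic dissected aorta.

    ``flap_offset`` is the signed perpendicular displacement (mm) of the flap
    chord from the lumen centre (0 = diameter chord); ``flap_angle`` orients
    the chord normal in-plane (radians).  ``centerline_amplitude`` is the
    peak in-plane drift (mm) of the tube centre along z.
    """

    n_slices: int = 40
    grid_shape: tuple[int, int] = (128, 128)
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    outer_diameter: float = 50.0
    flap_thickness: float = 2.4
    flap_offset: float = 10.0
    flap_angle: float = 0.6
    centerline_amplitude: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_slices < 1 or min(self.grid_shape) < 1:
            raise ValidationError("n_slices and grid_shape must be positive")
        if not all(s > 0 and np.isfinite(s) for s in self.spacing):
            raise ValidationError(f"spacing must be positive finite: {self.spacing}")
        if not 0 < self.flap_thickness < self.outer_diameter:
            raise ValidationError(
                f"flap_thickness must lie in (0, outer_diameter): "
                f"{self.flap_thickness} vs {self.outer_diameter}"
            )
        if abs(self.flap_offset) + self.flap_thickness / 2 >= self.outer_diameter / 2:
            raise ValidationError(
                "chord band must lie strictly inside the lumen: "
                f"|{self.flap_offset}| + {self.flap_thickness}/2 >= "
                f"{self.outer_diameter}/2"
            )
        ny, nx = self.grid_shape
        sy, sx = self.spacing[1], self.spacing[2]
        half_extent = min((ny - 1) * sy, (nx - 1) * sx) / 2
        reach = self.outer_diameter / 2 + abs(self.centerline_amplitude)
        if reach + 2 * max(sy, sx) > half_extent:
            raise ValidationError(
                f"outer diameter + drift ({reach:.1f} mm) does not fit in the "
                f"grid with a 2-voxel margin (half extent {half_extent:.1f} mm)"
            )


@dataclass(frozen=True)
class DegradationSpec:
    """Controlled imperfection applied to a ground-truth volume.

    ``boundary_shift_mm`` bounds a per-slice, per-label random morphological
    dilation/erosion radius; ``flip_fraction`` of TL/FL boundary voxels get
    their label swapped; ``dropout_slices`` whole slices are zeroed.
    """

    boundary_shift_mm: float = 0.0
    flip_fraction: float = 0.0
    dropout_slices: int = 0
    seed: int = 0

    def validate(self, phantom: PhantomSpec | None = None) -> None:
        if self.boundary_shift_mm < 0:
            raise ValidationError("boundary_shift_mm must be >= 0")
        if not 0 <= self.flip_fraction < 1:
            raise ValidationError("flip_fraction must lie in [0, 1)")
        if self.dropout_slices < 0:
            raise ValidationError("dropout_slices must be >= 0")
        if phantom is not None and self.boundary_shift_mm >= phantom.outer_diameter / 4:
            raise ValidationError(
                "boundary_shift_mm must be < outer_diameter/4 of the phantom"
            )


@dataclass(frozen=True)
class PhantomTruth:
    """Closed-form per-slice morphometry implied by a :class:`PhantomSpec`."""

    aortic_diameter: float
    tl_diameter: float
    fl_diameter: float
    tl_area: float
    fl_area: float
    flap_thickness: float
    flap_area: float


@dataclass(frozen=True)
class PhantomResult:
    annotation: LabelVolume  # flap band left as background
    full_truth: LabelVolume  # flap band labelled 3
    truth: PhantomTruth


def circular_segment_area(radius: float, cut: float) -> float:
    """Area of ``{p : p·n > cut}`` inside a disc of ``radius`` (cut may be <0)."""
    if cut >= radius:
        return 0.0
    if cut <= -radius:
        return math.pi * radius * radius
    return radius * radius * math.acos(cut / radius) - cut * math.sqrt(
        radius * radius - cut * cut
    )


def _segment_max_chord(radius: float, cut: float) -> float:
    """Maximum Feret diameter of the circular segment ``{p·n > cut}``."""
    if cut >= radius:
        return 0.0
    if cut <= 0:  # more than half the disc: contains a full diameter
        return 2 * radius
    return 2 * math.sqrt(radius * radius - cut * cut)


def analytic_truth(spec: PhantomSpec) -> PhantomTruth:
    """Closed-form morphometry of the phantom cross-section."""
    r = spec.outer_diameter / 2
    f = abs(spec.flap_offset)
    t = spec.flap_thickness
    cut_minor = f + t / 2  # cut distance for the smaller (TL) segment
    cut_major = t / 2 - f  # cut distance for the larger (FL) segment
    tl_area = circular_segment_area(r, cut_minor)
    fl_area = circular_segment_area(r, cut_major)
    flap_area = math.pi * r * r - tl_area - fl_area
    return PhantomTruth(
        aortic_diameter=spec.outer_diameter,
        tl_diameter=_segment_max_chord(r, cut_minor),
        fl_diameter=_segment_max_chord(r, cut_major),
        tl_area=tl_area,
        fl_area=fl_area,
        flap_thickness=t,
        flap_area=flap_area,
    )


def slice_center(spec: PhantomSpec, z: int) -> tuple[float, float]:
    """Physical (y, x) centre of the tube at slice ``z`` (sinusoidal drift)."""
    ny, nx = spec.grid_shape
    sy, sx = spec.spacing[1], spec.spacing[2]
    cy = (ny - 1) * sy / 2
    cx = (nx - 1) * sx / 2
    phase = 2 * math.pi * z / max(spec.n_slices, 1)
    return cy + spec.centerline_amplitude * math.sin(phase), cx


def generate_phantom(spec: PhantomSpec) -> PhantomResult:
    """Rasterize the phantom; deterministic for a given spec (incl. seed).

    Voxels are assigned by pixel-centre inclusion.  The smaller circular
    segment is TL, the larger FL; ties (offset 0) put TL on the positive side
    of the chord normal.
    """
    spec.validate()
    ny, nx = spec.grid_shape
    sy, sx = spec.spacing[1], spec.spacing[2]
    r = spec.outer_diameter / 2
    t2 = spec.flap_thickness / 2
    f = spec.flap_offset
    n_vec = (math.cos(spec.flap_angle), math.sin(spec.flap_angle))  # (y, x)
    # offset sign only mirrors the geometry; fold it into the normal
    if f < 0:
        n_vec = (-n_vec[0], -n_vec[1])
        f = -f

    yy = np.arange(ny)[:, None] * sy
    xx = np.arange(nx)[None, :] * sx
    ann = np.zeros((spec.n_slices, ny, nx), dtype=np.int16)
    full = np.zeros_like(ann)
    for z in range(spec.n_slices):
        cy, cx = slice_center(spec, z)
        dy = yy - cy
        dx = xx - cx
        inside = dy * dy + dx * dx <= r * r
        d = dy * n_vec[0] + dx * n_vec[1]  # signed distance from centre
        band = inside & (np.abs(d - f) <= t2)
        tl = inside & (d > f + t2)  # minor segment (ties: positive side)
        fl = inside & (d < f - t2)
        ann[z][tl] = TRUE_LUMEN
        ann[z][fl] = FALSE_LUMEN
        full[z] = ann[z]
        full[z][band] = FLAP
    truth = analytic_truth(spec)
    return PhantomResult(
        annotation=LabelVolume(ann, spec.spacing),
        full_truth=LabelVolume(full, spec.spacing),
        truth=truth,
    )


def _shift_mask(mask: np.ndarray, radius_px: int, grow: bool) -> np.ndarray:
    if radius_px <= 0:
        return mask
    selem = disk(radius_px)
    return dilation(mask, selem) if grow else erosion(mask, selem)


def degrade_prediction(gt: LabelVolume, spec: DegradationSpec) -> LabelVolume:
    """Produce a degraded "predicted" segmentation from a ground truth.

    Per slice and per label a random radius up to ``boundary_shift_mm``
    (converted to pixels via the in-plane spacing) dilates or erodes the
    mask; ``flip_fraction`` of TL/FL boundary voxels are label-swapped; and
    ``dropout_slices`` random slices are zeroed.  Deterministic given the
    seed; an all-zero spec returns the input unchanged.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sy, sx = gt.in_plane_spacing
    px = (sy + sx) / 2
    out = gt.voxels.copy()
    for z in range(gt.n_slices):
        sl = gt.voxels[z]
        new = sl.copy()
        if spec.boundary_shift_mm > 0:
            masks = {}
            for label in (TRUE_LUMEN, FALSE_LUMEN):
                radius_px = int(round(rng.uniform(0, spec.boundary_shift_mm) / px))
                grow = bool(rng.integers(0, 2))
                masks[label] = _shift_mask(sl == label, radius_px, grow)
            overlap = masks[TRUE_LUMEN] & masks[FALSE_LUMEN]
            new = np.zeros_like(sl)
            new[masks[FALSE_LUMEN]] = FALSE_LUMEN
            new[masks[TRUE_LUMEN]] = TRUE_LUMEN
            # contested voxels keep their original label where it was TL/FL
            new[overlap & (sl == FALSE_LUMEN)] = FALSE_LUMEN
        if spec.flip_fraction > 0:
            # boundary voxel: labelled TL or FL with an 8-neighbour of a
            # different value
            eight = np.ones((3, 3), bool)
            boundary = np.zeros_like(new, dtype=bool)
            for label in (TRUE_LUMEN, FALSE_LUMEN):
                m = new == label
                boundary |= m & ~ndi.binary_erosion(m, structure=eight)
            idx = np.flatnonzero(boundary)
            n_flip = int(round(spec.flip_fraction * idx.size))
            if n_flip:
                chosen = rng.choice(idx, size=n_flip, replace=False)
                flat = new.reshape(-1)
                flat[chosen] = np.where(
                    flat[chosen] == TRUE_LUMEN, FALSE_LUMEN, TRUE_LUMEN
                )
        out[z] = new
    if spec.dropout_slices > 0:
        n_drop = min(spec.dropout_slices, gt.n_slices)
        drop = rng.choice(gt.n_slices, size=n_drop, replace=False)
        out[drop] = BACKGROUND
    return LabelVolume(out, gt.spacing)


#: default attenuation levels (HU) per label for the visual-aid image
DEFAULT_HU_LEVELS = {BACKGROUND: 40.0, TRUE_LUMEN: 350.0, FALSE_LUMEN: 300.0, FLAP: 120.0}


def synthesize_intensity(
    gt: LabelVolume,
    noise_sd: float,
    levels: dict[int, float] | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Map labels to plausible contrast-CT attenuation plus Gaussian noise.

    Lumina are bright (contrast-filled), the flap intermediate, background
    dark.  Documentation/visualisation aid only — the analysis path never
    reads intensities.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    levels = dict(DEFAULT_HU_LEVELS if levels is None else levels)
    img = np.zeros(gt.shape, dtype=np.float64)
    for label, level in levels.items():
        img[gt.voxels == label] = level
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return img
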