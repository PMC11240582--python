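"""Read, write and slice multi-label segmentation volumes (NIfTI-1).

The package-wide label convention is::

    0  background
    1  true lumen (TL)
    2  false lumen (FL)
    3  intimal flap (present only after flap extraction)

Volumes are held internally in ``(z, y, x)`` axis order with 0-based indices;
the NIfTI reader reorients from the stored orientation (closest canonical) and
the writer emits a diagonal-affine file so that a write→read round trip is
bit-identical on voxels and exact on spacing.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import ValidationError, VolumeFormatError

#: canonical label codes
BACKGROUND, TRUE_LUMEN, FALSE_LUMEN, FLAP = 0, 1, 2, 3
VALID_LABELS = frozenset({BACKGROUND, TRUE_LUMEN, FALSE_LUMEN, FLAP})

#: tolerance when accepting float-stored labels as integers
_FLOAT_LABEL_ATOL = 1e-6


@dataclass
class LabelVolume:
    """A 3D integer label grid with physical voxel spacing.

    Parameters
    ----------
    voxels
        Integer array indexed ``(z, y, x)``.
    spacing
        Voxel size in mm per axis, ordered ``(z, y, x)``; all strictly
        positive and finite.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise VolumeFormatError(
                f"label volume must be 3D, got {self.voxels.ndim}D"
            )
        if not np.issubdtype(self.voxels.dtype, np.integer):
            rounded = np.rint(self.voxels)
            if not np.allclose(self.voxels, rounded, atol=_FLOAT_LABEL_ATOL):
                raise VolumeFormatError(
                    "voxel values are not integer-representable "
                    f"(max deviation {np.abs(self.voxels - rounded).max():.3g})"
                )
            self.voxels = rounded.astype(np.int16)
        if min(self.voxels.shape) < 1:
            raise ValidationError(f"empty grid axis in shape {self.voxels.shape}")
        bad = set(np.unique(self.voxels)) - VALID_LABELS
        if bad:
            raise ValidationError(
                f"labels outside {{0,1,2,3}} present: {sorted(int(b) for b in bad)}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or not all(
            np.isfinite(s) and s > 0 for s in self.spacing
        ):
            raise ValidationError(f"spacing must be 3 positive finite mm: {self.spacing}")

    # -- convenience ------------------------------------------------------

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.voxels.shape)

    @property
    def in_plane_spacing(self) -> tuple[float, float]:
        """(y, x) spacing in mm."""
        return self.spacing[1], self.spacing[2]

    def mask(self, label: int) -> np.ndarray:
        """Boolean grid of one label."""
        return self.voxels == label

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.voxels.copy(), self.spacing)


def read_label_volume(
    path: str | Path, label_remap: dict[int, int] | None = None
) -> LabelVolume:
    """Load a NIfTI-1 label volume, normalising axis order to (z, y, x).

    Float-stored labels within 1e-6 of an integer are accepted and rounded.
    ``label_remap`` translates foreign label codes to the package convention
    before validation (e.g. ``{5: 1, 6: 2}``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: expected 3D image, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]  # (x, y, z) in nibabel's data order
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    voxels = np.transpose(data, (2, 1, 0))  # (x, y, z) -> (z, y, x)
    if label_remap:
        voxels = np.rint(voxels).astype(np.int32)
        out = voxels.copy()
        for src, dst in label_remap.items():
            out[voxels == int(src)] = int(dst)
        voxels = out
    return LabelVolume(voxels, spacing)


def write_label_volume(volume: LabelVolume, path: str | Path) -> Path:
    """Write ``volume`` as NIfTI-1 so that :func:`read_label_volume` round-trips."""
    if not isinstance(volume, LabelVolume):
        volume = LabelVolume(volume.voxels, volume.spacing)  # re-validate
    path = Path(path)
    sz, sy, sx = volume.spacing
    data = np.transpose(volume.voxels, (2, 1, 0)).astype(np.int16)  # (x, y, z)
    affine = np.diag([sx, sy, sz, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((sx, sy, sz))
    nib.save(img, str(path))
    return path


def extract_slice(
    volume: LabelVolume, z: int
) -> tuple[np.ndarray, tuple[float, float]]:
    """Return the 2D (y, x) label grid at slice ``z`` and the (y, x) spacing."""
    if not 0 <= z < volume.n_slices:
        raise IndexError(f"slice index {z} out of range [0, {volume.n_slices})")
    return volume.voxels[z], volume.in_plane_spacing


def read_label_remap(path: str | Path) -> dict[int, int]:
    """Read a CSV remap table with columns (source_label, target_label)."""
    remap: dict[int, int] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            remap[int(row["source_label"])] = int(row["target_label"])
    return remap
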