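"""Stack per-slice labels into 3D surface meshes for visualisation.

The binary mask of one label is isosurfaced at 0.5 (marching cubes) with
vertex coordinates in physical mm, ``(z, y, x)`` order, and exported in a
standard triangle format (STL or PLY) via trimesh.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh
from skimage import measure

from .errors import ValidationError
from .volume_io import LabelVolume


@dataclass
class SurfaceMesh:
    """Triangle mesh of one label; vertices in mm, (z, y, x) order."""

    vertices: np.ndarray
    faces: np.ndarray
    label: int

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    @property
    def is_watertight(self) -> bool:
        return self.as_trimesh().is_watertight

    @property
    def enclosed_volume(self) -> float:
        """Volume in mm³ (meaningful for watertight meshes)."""
        return float(abs(self.as_trimesh().volume))

    def export(self, path: str | Path) -> Path:
        path = Path(path)
        self.as_trimesh().export(str(path))
        return path


def stack_to_mesh(
    volume: LabelVolume, label: int, smooth_passes: int = 0
) -> SurfaceMesh:
    """Isosurface of one label over the stacked slices.

    The mask is zero-padded by one voxel so surfaces close at the grid
    boundary.  ``smooth_passes`` applies that many rounds of Laplacian
    smoothing (off by default to preserve enclosed volume).
    """
    mask = volume.voxels == label
    if not mask.any():
        raise ValidationError(f"label {label} absent from volume")
    padded = np.pad(mask, 1).astype(np.uint8)
    verts, faces, _, _ = measure.marching_cubes(
        padded, level=0.5, spacing=volume.spacing
    )
    verts = verts - np.asarray(volume.spacing)  # undo the one-voxel pad
    mesh = SurfaceMesh(vertices=verts, faces=faces, label=label)
    if smooth_passes > 0:
        tm = mesh.as_trimesh()
        trimesh.smoothing.filter_laplacian(tm, iterations=smooth_passes)
        mesh = SurfaceMesh(
            vertices=np.asarray(tm.vertices), faces=np.asarray(tm.faces), label=label
        )
    return mesh
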