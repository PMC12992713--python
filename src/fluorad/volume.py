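"""Scan volumes and on-disk I/O.

A :class:`ScanVolume` is the in-memory form of one magnitude ¹⁹F MR
acquisition: a 3D scalar grid with anisotropic physical voxel spacing and
session/trial metadata.  Axes are (x, y, z) with z the slice direction, so
``data[:, :, k]`` is the k-th in-plane 64×64 (by default) slice.

Volumes and integer label masks are stored as NIfTI-1 files with the spacing
encoded in a diagonal affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

Spacing = tuple[float, float, float]

#: voxel spacing of the study's ¹⁹F protocol, mm
DEFAULT_SPACING: Spacing = (0.55, 0.55, 1.5)


@dataclass
class ScanVolume:
    """One 3D magnitude image plus physical geometry and trial metadata.

    Parameters
    ----------
    data:
        Non-negative scalar grid, shape ``(nx, ny, nz)``.
    spacing:
        Physical voxel size in mm per axis.
    meta:
        Free-form trial bookkeeping (experiment id, agent, session, arm,
        seed, ...).  Never interpreted numerically.
    """

    data: np.ndarray
    spacing: Spacing = DEFAULT_SPACING
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D grid, got shape {self.data.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in mm³."""
        return float(np.prod(self.spacing))

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical coordinates (mm) of voxel centers, one 1D array per axis.

        Voxel ``i`` along an axis with pitch ``d`` is centered at
        ``(i + 0.5) * d``, so the grid spans ``[0, n*d]``.
        """
        return tuple(
            (np.arange(n) + 0.5) * d for n, d in zip(self.shape, self.spacing)
        )

    def copy(self, data: np.ndarray | None = None, **meta) -> "ScanVolume":
        new_meta = {**self.meta, **meta}
        return ScanVolume(
            data=self.data.copy() if data is None else np.asarray(data, float),
            spacing=self.spacing,
            meta=new_meta,
        )


def _affine(spacing: Spacing) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    return aff


def save_volume(vol: ScanVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1; spacing goes into the affine."""
    path = Path(path)
    img = nib.Nifti1Image(vol.data.astype(np.float32), _affine(vol.spacing))
    nib.save(img, str(path))
    return path


def load_volume(path: str | Path, **meta) -> ScanVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ScanVolume(np.asarray(img.dataobj, dtype=float), spacing, dict(meta))


def save_labels(labels: np.ndarray, spacing: Spacing, path: str | Path) -> Path:
    """Write an integer label grid aligned voxel-for-voxel with its scan."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(labels, dtype=np.int16), _affine(spacing))
    nib.save(img, str(path))
    return path


def load_labels(path: str | Path) -> tuple[np.ndarray, Spacing]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj, dtype=int), spacing
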