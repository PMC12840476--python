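"""Axis-aligned 3D image volumes with world-coordinate metadata.

A :class:`Volume` is the universal carrier for CT intensities (HU),
probability maps, and binary/labelled masks.  Array index order is
``data[i, j, k]`` with axis ``i -> x``, ``j -> y``, ``k -> z``, so world
coordinates follow the annotation-CSV convention::

    world_mm = origin_mm + index * spacing_mm        (per axis, x/y/z)

Voxel indices are 0-based.  An axial slice is ``data[:, :, k]``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np


@dataclass
class Volume:
    """3D scalar grid plus spacing/origin metadata (all in mm)."""

    data: np.ndarray
    spacing_mm: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got shape {self.data.shape}")
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float).reshape(3)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float).reshape(3)
        if np.any(self.spacing_mm <= 0):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def copy_with(self, data: np.ndarray) -> "Volume":
        """New Volume sharing this volume's geometry."""
        return Volume(data, self.spacing_mm.copy(), self.origin_mm.copy())

    # ------------------------------------------------------------------
    # coordinate transforms
    # ------------------------------------------------------------------
    def world_to_voxel(self, p_mm) -> np.ndarray:
        """Continuous voxel index of world point(s) ``p_mm``.

        Out-of-grid indices are returned as-is (callers decide how to
        handle them); use :meth:`contains_index` to flag them.
        """
        p = np.asarray(p_mm, dtype=float)
        return (p - self.origin_mm) / self.spacing_mm

    def voxel_to_world(self, idx) -> np.ndarray:
        return self.origin_mm + np.asarray(idx, dtype=float) * self.spacing_mm

    def contains_index(self, idx) -> bool:
        idx = np.asarray(idx)
        return bool(np.all(idx >= 0) and np.all(idx <= np.array(self.shape) - 1))


@dataclass
class LungMask:
    """Binary lung-field mask aligned with its source volume."""

    mask: Volume

    def __post_init__(self) -> None:
        self.mask.data = self.mask.data.astype(bool)


# ----------------------------------------------------------------------
# file IO — MetaImage via SimpleITK, NIfTI via nibabel.
# Both libraries index arrays (z, y, x); we transpose to (x, y, z).
# ----------------------------------------------------------------------

def write_volume(v: Volume, path: str) -> None:
    path = os.fspath(path)
    if path.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag(list(v.spacing_mm) + [1.0])
        affine[:3, 3] = v.origin_mm
        nib.save(nib.Nifti1Image(np.asarray(v.data), affine), path)
    else:
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(v.data, (2, 1, 0))))
        img.SetSpacing(tuple(float(s) for s in v.spacing_mm))
        img.SetOrigin(tuple(float(o) for o in v.origin_mm))
        sitk.WriteImage(img, path)


def read_volume(path: str) -> Volume:
    path = os.fspath(path)
    if path.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(path)
        data = np.asanyarray(img.dataobj)
        spacing = np.abs(np.diag(img.affine)[:3])
        origin = img.affine[:3, 3]
        return Volume(data, spacing, origin)
    import SimpleITK as sitk

    img = sitk.ReadImage(path)
    data = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    return Volume(data, np.array(img.GetSpacing()), np.array(img.GetOrigin()))
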