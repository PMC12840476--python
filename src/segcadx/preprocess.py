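"""CT normalisation: isotropic resampling, HU windowing, lung masking.

All downstream stages assume 1 mm isotropic volumes windowed to
[-1000, 400] HU and linearly rescaled to [0, 1], with non-lung voxels
suppressed to the windowed air level (0).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .volume import LungMask, Volume

HU_WINDOW = (-1000.0, 400.0)


def resample_isotropic(v: Volume, target_mm: float = 1.0, *, is_mask: bool = False) -> Volume:
    """Resample to isotropic ``target_mm`` spacing.

    Trilinear interpolation for intensities, nearest-neighbour for masks.
    Output shape is ``round(shape * spacing / target)``; world origin is
    preserved, so the world extent changes by less than one voxel.
    """
    if target_mm <= 0:
        raise ValueError("target spacing must be positive")
    zoom = v.spacing_mm / target_mm
    new_shape = np.maximum(np.round(np.array(v.shape) * zoom).astype(int), 1)
    if np.allclose(v.spacing_mm, target_mm):
        return Volume(v.data.copy(), np.full(3, target_mm), v.origin_mm.copy())
    order = 0 if is_mask else 1
    data = ndimage.zoom(
        v.data.astype(np.float32, copy=False),
        new_shape / np.array(v.shape),
        order=order,
        mode="nearest",
        grid_mode=True,
    )
    if is_mask:
        data = data.astype(v.data.dtype)
    return Volume(data, np.full(3, target_mm), v.origin_mm.copy())


def hu_window_normalize(v: Volume, lo: float = HU_WINDOW[0], hi: float = HU_WINDOW[1]) -> Volume:
    """Clip to [lo, hi] HU and rescale linearly to [0, 1]."""
    if lo >= hi:
        raise ValueError("window lower bound must be below upper bound")
    out = np.clip((v.data.astype(np.float32) - lo) / (hi - lo), 0.0, 1.0)
    return v.copy_with(out)


def lung_mask_postprocess(prob: Volume, thr: float = 0.5, closing_radius_vox: int = 3) -> LungMask:
    """Threshold a lung-probability map, close gaps, and fill holes.

    Closing uses a ball of ``closing_radius_vox`` voxels — the smallest
    element that bridges vessel-induced gaps at 1 mm spacing.
    """
    binary = prob.data >= thr
    if binary.any():
        r = closing_radius_vox
        zz, yy, xx = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
        ball = (zz**2 + yy**2 + xx**2) <= r**2
        binary = ndimage.binary_closing(binary, structure=ball)
        binary = ndimage.binary_fill_holes(binary)
    return LungMask(prob.copy_with(binary))


def apply_lung_mask(v: Volume, m: LungMask) -> Volume:
    """Zero voxels outside the lung mask (0 = normalized air level)."""
    if v.shape != m.mask.shape:
        raise ValueError(f"shape mismatch: {v.shape} vs {m.mask.shape}")
    out = np.where(m.mask.data, v.data, 0.0).astype(np.float32)
    return v.copy_with(out)


def world_to_voxel(p_mm, v: Volume) -> np.ndarray:
    return v.world_to_voxel(p_mm)


def voxel_to_world(idx, v: Volume) -> np.ndarray:
    return v.voxel_to_world(idx)


def preprocess_scan(v: Volume, lung_mask: Volume | None = None, target_mm: float = 1.0) -> tuple[Volume, LungMask | None]:
    """Standard chain: resample -> window/normalize -> apply lung mask."""
    iso = resample_isotropic(v, target_mm)
    norm = hu_window_normalize(iso)
    if lung_mask is None:
        return norm, None
    iso_mask = resample_isotropic(lung_mask, target_mm, is_mask=True)
    lm = LungMask(iso_mask)
    return apply_lung_mask(norm, lm), lm
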