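"""Image conditioning: rolling-ball background subtraction, world-unit
Gaussian smoothing, hemisphere flipping and atlas-based exclusion masking.

The rolling-ball step is implemented as slice-wise grayscale opening with a
flat disk of the given pixel radius (the standard morphological equivalent),
applied to each z-slice independently.  Smoothing takes its sigma in
millimetres of world space (fslmaths ``-s`` convention) and converts to
per-axis voxel sigmas via the grid spacing; boundaries are zero-padded.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .volume_core import LabelVolume, ScalarVolume, UsageError


def rolling_ball_subtract(vol: ScalarVolume, radius_px: int = 20) -> ScalarVolume:
    """Subtract, slice by slice in z, the grayscale opening with a flat disk
    of radius ``radius_px``; output is >= 0 and <= input everywhere."""
    radius_px = int(radius_px)
    if radius_px < 1:
        raise UsageError("rolling-ball radius must be a positive integer")
    footprint = disk(radius_px).astype(bool)
    out = np.empty_like(vol.values)
    for k in range(vol.grid.shape[2]):
        sl = vol.values[:, :, k]
        opened = ndimage.grey_opening(sl, footprint=footprint, mode="nearest")
        out[:, :, k] = sl - opened
    np.maximum(out, 0.0, out=out)  # guard float round-off
    return ScalarVolume(vol.grid, out)


def gaussian_smooth(vol: ScalarVolume, sigma_world_mm: float = 0.05) -> ScalarVolume:
    """Isotropic Gaussian smoothing; ``sigma_world_mm`` is the kernel sigma in
    millimetres, converted per axis to voxels.  Sigma 0 is the identity."""
    if sigma_world_mm < 0:
        raise UsageError("smoothing sigma must be >= 0")
    if sigma_world_mm == 0:
        return vol.copy()
    sigma_um = sigma_world_mm * 1000.0
    sigmas = [sigma_um / s for s in vol.grid.spacing]
    # truncate=6 keeps >1-1e-8 of the kernel mass (4-sigma tails lose ~2e-4)
    out = ndimage.gaussian_filter(
        vol.values, sigma=sigmas, mode="constant", cval=0.0, truncate=6.0
    )
    return ScalarVolume(vol.grid, out)


def flip_left_to_right(vol):
    """Mirror across the mid-sagittal plane: x -> shape_x - 1 - x."""
    if isinstance(vol, LabelVolume):
        return LabelVolume(vol.grid, vol.labels[::-1].copy(), vol.region_table)
    return ScalarVolume(vol.grid, vol.values[::-1].copy())


def exclusion_mask(atlas: LabelVolume) -> np.ndarray:
    """Boolean analysis mask: labelled voxels whose region is not excluded."""
    mask = atlas.labels != 0
    for label in atlas.region_table.excluded_labels():
        mask &= atlas.labels != label
    return mask
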