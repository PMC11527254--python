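"""NIfTI-1 / TIFF input-output for volumes and CSV for region tables."""

from __future__ import annotations

import numpy as np
import nibabel as nib
import tifffile

from .volume_core import (
    GeometryError,
    LabelVolume,
    RegionTable,
    ScalarVolume,
    VoxelGrid,
)


def _grid_from_nifti(img: nib.Nifti1Image) -> VoxelGrid:
    aff = img.affine
    linear = aff[:3, :3]
    off_diag = linear - np.diag(np.diag(linear))
    if np.abs(off_diag).max() > 1e-6 * max(1.0, np.abs(linear).max()):
        raise GeometryError("only axis-aligned (diagonal) NIfTI affines are supported")
    spacing = np.diag(linear)
    if np.any(spacing <= 0):
        raise GeometryError("negative/zero spacing in NIfTI affine is not supported")
    origin = aff[:3, 3] - 0.5 * spacing
    return VoxelGrid(tuple(img.shape[:3]), tuple(spacing), tuple(origin))


def save_nifti(vol: ScalarVolume | LabelVolume, path) -> None:
    if isinstance(vol, LabelVolume):
        data = vol.labels.astype(np.int32)
    else:
        data = vol.values.astype(np.float32)
    img = nib.Nifti1Image(data, vol.grid.affine())
    img.header.set_xyzt_units(xyz="micron")
    nib.save(img, str(path))


def load_scalar_nifti(path) -> ScalarVolume:
    img = nib.load(str(path))
    return ScalarVolume(_grid_from_nifti(img), np.asarray(img.dataobj, dtype=float))


def load_label_nifti(path, region_table: RegionTable) -> LabelVolume:
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj)
    return LabelVolume(_grid_from_nifti(img), labels.astype(np.int32), region_table)


def load_tiff_stack(path, spacing, origin=(0.0, 0.0, 0.0)) -> ScalarVolume:
    """Import a z-series TIFF as (x, y, z); spacing must be supplied since
    TIFF carries no 3D geometry."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    # tifffile yields (z, y, x); reorder to (x, y, z)
    arr = np.transpose(arr, (2, 1, 0))
    grid = VoxelGrid(arr.shape, tuple(spacing), tuple(origin))
    return ScalarVolume(grid, arr.astype(float))


def save_tiff_stack(vol: ScalarVolume, path) -> None:
    tifffile.imwrite(
        str(path),
        np.transpose(vol.values, (2, 1, 0)).astype(np.float32),
        photometric="minisblack",
    )
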