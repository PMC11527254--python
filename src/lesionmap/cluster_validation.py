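"""Tissue-space cluster validation: cell/fiber partitioning, segmentation,
3D cell counting, fiber density, per-cluster unpaired t-tests and
region-wise density tables.

Counting rule: a connected component of the segmentation is attributed to a
cluster (or atlas region) when its centroid voxel lies inside the mask; this
avoids double counting objects straddling the cell/fiber partition boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .volume_core import (
    AffineTransform,
    GeometryError,
    LabelVolume,
    ScalarVolume,
    UsageError,
    VoxelGrid,
    apply_affine,
)
from .fdr_clustering import _STRUCTURES


class UndefinedDensityError(ValueError):
    """Raised when a density is requested for an empty cluster."""


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def partition_cluster(
    cluster_mask: np.ndarray, cellgroup_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Split a cluster into its cell-group part (within dopaminergic or
    noradrenergic regions) and the fiber remainder; disjoint, covering."""
    if cluster_mask.shape != cellgroup_mask.shape:
        raise GeometryError("cluster and cell-group masks must share a shape")
    cell = cluster_mask & cellgroup_mask
    fiber = cluster_mask & ~cellgroup_mask
    return cell, fiber


def warp_cluster(
    cluster_mask: np.ndarray,
    atlas_grid: VoxelGrid,
    t: AffineTransform,
    tissue_grid: VoxelGrid,
) -> np.ndarray:
    """Nearest-neighbour warp of a binary cluster mask onto the tissue grid.

    ``t`` maps atlas world coordinates to tissue world coordinates."""
    vol = ScalarVolume(atlas_grid, cluster_mask.astype(float))
    out = apply_affine(vol, t, tissue_grid, mode="nearest")
    return out.values > 0.5


def mask_volume_mm3(mask: np.ndarray, grid: VoxelGrid) -> float:
    return float(mask.sum()) * grid.voxel_volume_mm3


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_signal(
    raw: ScalarVolume,
    method: Literal["quantile_threshold", "otsu", "external_mask"] = "quantile_threshold",
    quantile: float = 0.98,
    min_size: int = 2,
    external: Optional[np.ndarray] = None,
    within: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Deterministic stand-in for interactive classifier output.

    quantile_threshold keeps voxels above the given intensity quantile
    (computed over ``within`` if supplied, else the whole volume); otsu uses
    Otsu's threshold; external_mask passes a user-supplied binary volume
    through the same speck filter.  Objects smaller than ``min_size`` voxels
    (26-connectivity) are removed.
    """
    if method == "external_mask":
        if external is None:
            raise UsageError("external_mask requires an `external` binary volume")
        if external.shape != raw.grid.shape:
            raise GeometryError("external mask shape mismatch")
        seg = external.astype(bool)
    else:
        values = raw.values[within] if within is not None else raw.values
        if method == "quantile_threshold":
            if not (0.0 < quantile < 1.0):
                raise UsageError("quantile must lie in (0, 1)")
            thr = np.quantile(values, quantile)
        elif method == "otsu":
            from skimage.filters import threshold_otsu

            thr = threshold_otsu(values)
        else:
            raise UsageError(f"unknown segmentation method {method!r}")
        seg = raw.values > thr
        if within is not None:
            seg &= within

    if min_size > 1 and seg.any():
        lab, n = ndimage.label(seg, structure=_STRUCTURES[26])
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= min_size) + 1
        seg = np.isin(lab, keep)
    return seg


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

def _component_centroids(seg: np.ndarray) -> tuple[np.ndarray, int]:
    """Label segmentation (26-connectivity) and return integer centroid
    voxels, shape (n, 3)."""
    lab, n = ndimage.label(seg, structure=_STRUCTURES[26])
    if n == 0:
        return np.empty((0, 3), int), 0
    cents = np.asarray(ndimage.center_of_mass(seg, lab, np.arange(1, n + 1)))
    return np.round(cents).astype(int), n


def count_cells(
    segmentation: np.ndarray,
    cluster_mask: np.ndarray,
    grid: VoxelGrid,
) -> tuple[int, float]:
    """Count 26-connected components whose centroid lies in ``cluster_mask``;
    density in cells/mm^3 of the cluster volume."""
    if segmentation.shape != cluster_mask.shape:
        raise GeometryError("segmentation and cluster mask must share a shape")
    n_cluster = int(cluster_mask.sum())
    if n_cluster == 0:
        raise UndefinedDensityError("empty cluster mask")
    cents, n = _component_centroids(segmentation)
    if n == 0:
        return 0, 0.0
    cents = np.clip(cents, 0, np.asarray(segmentation.shape) - 1)
    inside = cluster_mask[cents[:, 0], cents[:, 1], cents[:, 2]]
    count = int(inside.sum())
    return count, count / (n_cluster * grid.voxel_volume_mm3)


def fiber_density(segmentation: np.ndarray, cluster_mask: np.ndarray) -> float:
    """100 x |segmentation AND cluster| / |cluster| (percent)."""
    if segmentation.shape != cluster_mask.shape:
        raise GeometryError("segmentation and cluster mask must share a shape")
    n_cluster = int(cluster_mask.sum())
    if n_cluster == 0:
        raise UndefinedDensityError("empty cluster mask")
    return 100.0 * int((segmentation & cluster_mask).sum()) / n_cluster


# ---------------------------------------------------------------------------
# validation statistics
# ---------------------------------------------------------------------------

@dataclass
class ValidationResult:
    cluster_id: int
    measure: str
    t: float
    p: float
    valid: bool
    direction: int  # sign of mean(A) - mean(B)
    n_a: int
    n_b: int


def validate_cluster(
    values_a: Sequence[float],
    values_b: Sequence[float],
    alpha: float = 0.05,
    cluster_id: int = 0,
    measure: str = "density",
) -> ValidationResult:
    """Unpaired two-tailed pooled-variance t-test; valid iff p < alpha."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size < 2 or b.size < 2:
        raise UsageError("need at least 2 values per group")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    if np.isnan(t):  # both groups constant and equal
        t, p = 0.0, 1.0
    diff = a.mean() - b.mean()
    return ValidationResult(
        cluster_id=cluster_id,
        measure=measure,
        t=float(t),
        p=float(p),
        valid=bool(p < alpha),
        direction=int(np.sign(diff)),
        n_a=int(a.size),
        n_b=int(b.size),
    )


def regionwise_densities(
    atlas: LabelVolume, segmentation: np.ndarray, grid: Optional[VoxelGrid] = None
) -> pd.DataFrame:
    """Per-region component counts (centroid rule), volumes and densities."""
    grid = grid or atlas.grid
    if segmentation.shape != atlas.labels.shape:
        raise GeometryError("segmentation must match the atlas lattice")
    cents, n = _component_centroids(segmentation)
    labels_at = (
        atlas.labels[cents[:, 0], cents[:, 1], cents[:, 2]] if n else np.empty(0, int)
    )
    rows = []
    for label_id in atlas.region_table.label_ids:
        count = int(np.sum(labels_at == label_id))
        nvox = int(np.sum(atlas.labels == label_id))
        vol = nvox * grid.voxel_volume_mm3
        rows.append(
            dict(
                label_id=int(label_id),
                region=atlas.region_table.name_of(int(label_id)),
                count=count,
                region_voxels=nvox,
                volume_mm3=vol,
                density_per_mm3=count / vol if vol > 0 else 0.0,
            )
        )
    return pd.DataFrame(rows)


def region_anova_tukey(groups: dict[str, Sequence[float]]) -> pd.DataFrame:
    """One-way ANOVA followed by Tukey HSD adjusted pairwise comparisons."""
    names = list(groups)
    arrays = [np.asarray(groups[g], float) for g in names]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise UsageError("need >= 2 groups with >= 2 samples each")
    if len(set(a.ndim for a in arrays)) != 1 or any(a.ndim != 1 for a in arrays):
        raise UsageError("each group must be a flat sequence of values")
    f_stat, f_p = stats.f_oneway(*arrays)
    res = stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append(
                dict(
                    group_a=names[i],
                    group_b=names[j],
                    mean_diff=float(arrays[i].mean() - arrays[j].mean()),
                    p_adj=float(res.pvalue[i, j]),
                    anova_F=float(f_stat),
                    anova_p=float(f_p),
                )
            )
    return pd.DataFrame(rows)
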