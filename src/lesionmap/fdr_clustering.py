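"""Benjamini-Hochberg FDR with cluster-size-constrained q selection,
3D connected-component labelling and direction splitting.

The q-selection rule: scan a grid of q values and keep the smallest
(most stringent) q at which at least one connected component of
suprathreshold voxels still has at least ``min_cluster`` voxels; all
reported clusters must meet the size floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume_core import GeometryError, LabelVolume, UsageError, VoxelGrid
from .voxelwise_stats import StatMap

DEFAULT_Q_GRID = (0.05, 0.01, 0.005, 0.001, 0.0005, 0.0001, 0.00005)

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


# ---------------------------------------------------------------------------
# BH step-up
# ---------------------------------------------------------------------------

def bh_threshold(pvals: Sequence[float], q: float) -> tuple[float, int]:
    """Step-up BH threshold: the largest sorted p_(i) with p_(i) <= (i/m)q.

    Returns (threshold, n_significant); (0.0, 0) when nothing passes.
    Ties at the threshold are all retained (<= comparison).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise UsageError("empty p-value list")
    if not (0 < q < 1):
        raise UsageError("q must lie in (0, 1)")
    if p.min() < 0 or p.max() > 1:
        raise UsageError("p-values must lie in [0, 1]")
    m = p.size
    order = np.sort(p)
    crit = (np.arange(1, m + 1) / m) * q
    passing = np.nonzero(order <= crit)[0]
    if passing.size == 0:
        return 0.0, 0
    threshold = float(order[passing[-1]])
    # note: threshold may legitimately be 0.0 when p-values of exactly 0 occur
    return threshold, int(np.sum(p <= threshold))


# ---------------------------------------------------------------------------
# clusters
# ---------------------------------------------------------------------------

@dataclass
class ClusterSet:
    """Labelled connected components of significant voxels."""

    labels: np.ndarray  # 0 = background, 1..K cluster ids
    grid: VoxelGrid
    table: pd.DataFrame  # cluster_id, n_voxels, direction, contrast, q, p_threshold,
    # centroid_{x,y,z}, bbox, composition (dict label -> (count, fraction))
    connectivity: int = 26

    @property
    def n_clusters(self) -> int:
        return int(self.table.shape[0])

    def mask_of(self, cluster_id: int) -> np.ndarray:
        return self.labels == cluster_id

    def empty(self) -> bool:
        return self.n_clusters == 0


def _relabel_by_size(labeled: np.ndarray, n: int) -> tuple[np.ndarray, list[int]]:
    """Relabel components 1..n in decreasing size; ties broken by the
    lexicographically smallest voxel index."""
    if n == 0:
        return labeled, []
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=np.arange(1, n + 1))
    # lexicographic minimum voxel per component
    flat_first = np.full(n + 1, np.iinfo(np.int64).max, dtype=np.int64)
    flat_idx = np.flatnonzero(labeled.ravel())
    np.minimum.at(flat_first, labeled.ravel()[flat_idx], flat_idx)
    order = sorted(range(1, n + 1), key=lambda l: (-sizes[l - 1], flat_first[l]))
    remap = np.zeros(n + 1, dtype=labeled.dtype)
    for new, old in enumerate(order, start=1):
        remap[old] = new
    return remap[labeled], [int(sizes[l - 1]) for l in order]


def label_clusters(
    mask: np.ndarray, connectivity: Literal[6, 18, 26] = 26
) -> tuple[np.ndarray, list[int]]:
    """Connected components of ``mask``; labels sorted by decreasing size.

    Returns (label volume, sizes ordered by label id).
    """
    if connectivity not in _STRUCTURES:
        raise UsageError("connectivity must be 6, 18 or 26")
    labeled, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    return _relabel_by_size(labeled, n)


def _centroids(labels: np.ndarray, ids: Sequence[int]) -> list[tuple[float, float, float]]:
    if not len(ids):
        return []
    return [tuple(map(float, c)) for c in ndimage.center_of_mass(labels > 0, labels, ids)]


def _bboxes(labels: np.ndarray, n: int) -> list[tuple]:
    slices = ndimage.find_objects(labels, max_label=n)
    out = []
    for sl in slices:
        if sl is None:
            out.append(None)
        else:
            out.append(tuple((s.start, s.stop) for s in sl))
    return out


def _build_table(
    labels: np.ndarray,
    sizes: Sequence[int],
    contrast: str,
    q: Optional[float],
    p_threshold: Optional[float],
    directions: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    ids = list(range(1, len(sizes) + 1))
    cents = _centroids(labels, ids)
    boxes = _bboxes(labels, len(sizes))
    rows = []
    for i, cid in enumerate(ids):
        rows.append(
            dict(
                cluster_id=cid,
                contrast=contrast,
                direction=0 if directions is None else int(directions[i]),
                q=q,
                p_threshold=p_threshold,
                n_voxels=int(sizes[i]),
                centroid_x=cents[i][0],
                centroid_y=cents[i][1],
                centroid_z=cents[i][2],
                bbox=boxes[i],
            )
        )
    columns = [
        "cluster_id", "contrast", "direction", "q", "p_threshold", "n_voxels",
        "centroid_x", "centroid_y", "centroid_z", "bbox",
    ]
    return pd.DataFrame(rows, columns=columns)


@dataclass
class FDRResult:
    """Outcome of cluster-constrained FDR on one contrast's p-map."""

    q: Optional[float]
    p_threshold: float
    m: int
    n_significant: int
    clusters: ClusterSet
    no_signal: bool = False

    @property
    def has_signal(self) -> bool:
        return not self.no_signal and not self.clusters.empty()


def select_q(
    pmap: StatMap,
    q_grid: Sequence[float] = DEFAULT_Q_GRID,
    min_cluster: int = 100,
    connectivity: Literal[6, 18, 26] = 26,
    contrast: Optional[str] = None,
    restrict: Optional[np.ndarray] = None,
) -> FDRResult:
    """Pick the most stringent q in ``q_grid`` that still leaves at least one
    cluster of >= ``min_cluster`` significant voxels; report its clusters.

    ``restrict`` optionally limits the comparisons (e.g. to post hoc gate
    voxels); m is the number of p-values actually tested.
    """
    if len(q_grid) == 0:
        raise UsageError("q_grid must be non-empty")
    if min_cluster < 1:
        raise UsageError("min_cluster must be >= 1")
    name = contrast or pmap.metadata.get("contrast", "contrast")

    p_flat = pmap.p if restrict is None else pmap.p[restrict]
    m = int(p_flat.size)
    if m == 0:
        empty = ClusterSet(np.zeros(pmap.grid.shape, np.int32), pmap.grid,
                           _build_table(np.zeros(pmap.grid.shape, np.int32), [], name, None, 0.0),
                           connectivity)
        return FDRResult(None, 0.0, 0, 0, empty, no_signal=True)

    best = None
    for q in sorted(set(float(q) for q in q_grid)):  # ascending stringency order
        threshold, n_sig = bh_threshold(p_flat, q)
        if n_sig == 0:
            continue
        sig_flat = np.zeros(pmap.p.size, dtype=bool)
        if restrict is None:
            sig_flat = pmap.p <= threshold
        else:
            idx = np.flatnonzero(restrict)
            sig_flat[idx[p_flat <= threshold]] = True
        sig_vol = np.zeros(pmap.grid.shape, dtype=bool)
        sig_vol[pmap.mask] = sig_flat
        labels, sizes = label_clusters(sig_vol, connectivity)
        if sizes and sizes[0] >= min_cluster:
            best = (q, threshold, n_sig, labels, sizes)
            break  # smallest qualifying q found (grid scanned ascending)

    if best is None:
        empty = ClusterSet(
            np.zeros(pmap.grid.shape, np.int32),
            pmap.grid,
            _build_table(np.zeros(pmap.grid.shape, np.int32), [], name, None, 0.0),
            connectivity,
        )
        return FDRResult(None, 0.0, m, 0, empty, no_signal=True)

    q, threshold, n_sig, labels, sizes = best
    # drop sub-minimum clusters from the reported set
    keep = [i + 1 for i, s in enumerate(sizes) if s >= min_cluster]
    filtered = np.where(np.isin(labels, keep), labels, 0)
    filtered, kept_sizes = _relabel_by_size(filtered, len(keep))
    table = _build_table(filtered, kept_sizes, name, q, threshold)
    clusters = ClusterSet(filtered.astype(np.int32), pmap.grid, table, connectivity)
    return FDRResult(q, threshold, m, n_sig, clusters)


def split_by_direction(
    clusters: ClusterSet,
    sign_volume: np.ndarray,
    min_cluster: int = 100,
) -> ClusterSet:
    """Re-label clusters into sign-homogeneous components.

    Zero-sign voxels take the majority sign of their 26-neighbours within the
    cluster; unresolved ties are excluded.  Components are re-filtered by
    ``min_cluster`` and relabelled by decreasing size.
    """
    if sign_volume.shape != clusters.labels.shape:
        raise GeometryError("sign volume must match the cluster grid")
    sign = np.sign(sign_volume).astype(np.int8)
    in_cluster = clusters.labels > 0

    zeros = in_cluster & (sign == 0)
    if np.any(zeros):
        kernel = _STRUCTURES[26].astype(float)
        kernel[1, 1, 1] = 0.0
        pos = ndimage.convolve(((sign > 0) & in_cluster).astype(float), kernel, mode="constant")
        neg = ndimage.convolve(((sign < 0) & in_cluster).astype(float), kernel, mode="constant")
        sign = sign.copy()
        sign[zeros & (pos > neg)] = 1
        sign[zeros & (neg > pos)] = -1
        # remaining ties stay 0 and are excluded

    pieces = []
    for s in (1, -1):
        m = in_cluster & (sign == s)
        lab, sizes = label_clusters(m, clusters.connectivity)  # type: ignore[arg-type]
        for cid, size in enumerate(sizes, start=1):
            if size >= min_cluster:
                pieces.append((s, lab == cid, size))
    pieces.sort(key=lambda t: -t[2])

    out_labels = np.zeros_like(clusters.labels)
    directions = []
    sizes = []
    for new_id, (s, m, size) in enumerate(pieces, start=1):
        out_labels[m] = new_id
        directions.append(s)
        sizes.append(size)

    base = clusters.table
    contrast = base["contrast"].iloc[0] if len(base) else ""
    q = base["q"].iloc[0] if len(base) else None
    thr = base["p_threshold"].iloc[0] if len(base) else None
    table = _build_table(out_labels, sizes, contrast, q, thr, directions)
    return ClusterSet(out_labels, clusters.grid, table, clusters.connectivity)


def cluster_composition(clusters: ClusterSet, atlas: LabelVolume) -> pd.DataFrame:
    """Per-cluster voxel counts and fractions per atlas label."""
    if atlas.grid.shape != clusters.grid.shape:
        raise GeometryError("atlas and cluster grids must match")
    rows = []
    for cid in clusters.table["cluster_id"]:
        m = clusters.labels == cid
        total = int(m.sum())
        vals, counts = np.unique(atlas.labels[m], return_counts=True)
        for v, c in zip(vals, counts):
            name = "unlabelled" if v == 0 else atlas.region_table.name_of(int(v))
            rows.append(
                dict(
                    cluster_id=int(cid),
                    label_id=int(v),
                    region=name,
                    n_voxels=int(c),
                    fraction=c / total,
                )
            )
    return pd.DataFrame(
        rows, columns=["cluster_id", "label_id", "region", "n_voxels", "fraction"]
    )
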