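"""Core lattice types and geometric primitives.

Conventions
-----------
* 0-based voxel indices; the world coordinate of voxel ``v`` is
  ``origin + (v + 0.5) * spacing`` (voxel-centre convention).
* Axes are anatomical: x = left->right, y = posterior->anterior,
  z = inferior->superior.  Lengths are in micrometres unless noted.
* Out-of-bounds samples are filled with 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage


class UsageError(ValueError):
    """Raised when an operation is called with invalid parameters."""


class GeometryError(ValueError):
    """Raised when volumes/transforms disagree on geometry."""


class InvalidTransformError(ValueError):
    """Raised for singular or inconsistent affine transforms."""


CellGroup = Literal["dopaminergic", "noradrenergic", "none"]


# ---------------------------------------------------------------------------
# grids and volumes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VoxelGrid:
    """A 3D sampling lattice with spacing (um), origin (um) and axis tag."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = "RAS"

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise UsageError(f"shape must be 3 positive integers, got {self.shape}")
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise UsageError(f"spacing must be 3 positive lengths, got {self.spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    # -- coordinate maps ----------------------------------------------------
    def world_from_voxel(self, idx: np.ndarray) -> np.ndarray:
        """World coordinates of voxel indices ``idx`` (..., 3)."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + (idx + 0.5) * np.asarray(self.spacing)

    def voxel_from_world(self, xyz: np.ndarray) -> np.ndarray:
        """Fractional voxel indices of world points ``xyz`` (..., 3)."""
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - np.asarray(self.origin)) / np.asarray(self.spacing) - 0.5

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_mm3(self) -> float:
        return self.voxel_volume_um3 * 1e-9

    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world affine (nibabel convention)."""
        a = np.eye(4)
        a[:3, :3] = np.diag(self.spacing)
        a[:3, 3] = np.asarray(self.origin) + 0.5 * np.asarray(self.spacing)
        return a

    def index_grid_world(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape (*shape, 3)."""
        idx = np.stack(
            np.meshgrid(*(np.arange(s) for s in self.shape), indexing="ij"), axis=-1
        )
        return self.world_from_voxel(idx)


@dataclass
class ScalarVolume:
    """A scalar field (fluorescence or statistic values) on a VoxelGrid."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise GeometryError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise UsageError("ScalarVolume values must be finite")

    def copy(self) -> "ScalarVolume":
        return ScalarVolume(self.grid, self.values.copy())


@dataclass
class RegionTable:
    """Per-label atlas metadata.

    Columns: label_id (unique, positive), name, parent_id (nullable),
    cell_group in {dopaminergic, noradrenergic, none}, excluded (bool).
    """

    df: pd.DataFrame

    COLUMNS = ("label_id", "name", "parent_id", "cell_group", "excluded")

    def __post_init__(self) -> None:
        df = self.df.copy()
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise UsageError(f"RegionTable missing columns: {sorted(missing)}")
        df["label_id"] = df["label_id"].astype(int)
        if (df["label_id"] <= 0).any():
            raise UsageError("label_id must be positive (0 is reserved for outside)")
        if df["label_id"].duplicated().any():
            raise UsageError("label_id values must be unique")
        bad = ~df["cell_group"].isin(["dopaminergic", "noradrenergic", "none"])
        if bad.any():
            raise UsageError(f"invalid cell_group values: {df.loc[bad, 'cell_group'].tolist()}")
        df["excluded"] = df["excluded"].astype(bool)
        self._check_acyclic(df)
        self.df = df.reset_index(drop=True)

    @staticmethod
    def _check_acyclic(df: pd.DataFrame) -> None:
        parent = {
            int(r.label_id): (None if pd.isna(r.parent_id) else int(r.parent_id))
            for r in df.itertuples()
        }
        for start in parent:
            seen = {start}
            node = parent[start]
            while node is not None and node in parent:
                if node in seen:
                    raise UsageError(f"cyclic parent links involving label {node}")
                seen.add(node)
                node = parent[node]

    @classmethod
    def from_rows(cls, rows: Iterable[dict]) -> "RegionTable":
        return cls(pd.DataFrame(list(rows), columns=list(cls.COLUMNS)))

    @property
    def label_ids(self) -> np.ndarray:
        return self.df["label_id"].to_numpy()

    def name_of(self, label_id: int) -> str:
        row = self.df[self.df["label_id"] == label_id]
        if row.empty:
            raise KeyError(f"label {label_id} not in region table")
        return str(row["name"].iloc[0])

    def excluded_labels(self) -> np.ndarray:
        return self.df.loc[self.df["excluded"], "label_id"].to_numpy()

    def cell_group_labels(self) -> np.ndarray:
        """Labels flagged dopaminergic or noradrenergic."""
        sel = self.df["cell_group"].isin(["dopaminergic", "noradrenergic"])
        return self.df.loc[sel, "label_id"].to_numpy()

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RegionTable":
        return cls(pd.read_csv(path))


@dataclass
class LabelVolume:
    """Integer-labelled lattice (0 = outside brain) plus region metadata."""

    grid: VoxelGrid
    labels: np.ndarray
    region_table: RegionTable

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.allclose(self.labels, np.round(self.labels)):
                raise UsageError("labels must be integers")
            self.labels = np.round(self.labels).astype(np.int32)
        if self.labels.shape != self.grid.shape:
            raise GeometryError(
                f"labels shape {self.labels.shape} != grid shape {self.grid.shape}"
            )
        if self.labels.min() < 0:
            raise UsageError("labels must be non-negative")
        present = set(np.unique(self.labels)) - {0}
        known = set(int(x) for x in self.region_table.label_ids)
        unknown = present - known
        if unknown:
            raise UsageError(f"labels missing from region table: {sorted(unknown)}")

    def mask_of(self, label_ids: int | Sequence[int]) -> np.ndarray:
        if np.isscalar(label_ids):
            return self.labels == int(label_ids)
        return np.isin(self.labels, np.asarray(label_ids, dtype=int))

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.grid, self.labels.copy(), self.region_table)


# ---------------------------------------------------------------------------
# affine transforms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AffineTransform:
    """World-to-world affine map ``x -> linear @ x + offset``."""

    linear: np.ndarray
    offset: np.ndarray
    direction: str = "tissue->atlas"

    def __post_init__(self) -> None:
        linear = np.asarray(self.linear, dtype=float).reshape(3, 3)
        offset = np.asarray(self.offset, dtype=float).reshape(3)
        if abs(np.linalg.det(linear)) < 1e-12:
            raise InvalidTransformError("linear part is singular")
        object.__setattr__(self, "linear", linear)
        object.__setattr__(self, "offset", offset)

    @classmethod
    def identity(cls, direction: str = "tissue->atlas") -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3), direction)

    @classmethod
    def translation(cls, shift, direction: str = "tissue->atlas") -> "AffineTransform":
        return cls(np.eye(3), np.asarray(shift, dtype=float), direction)

    @classmethod
    def scaling(cls, factors, direction: str = "tissue->atlas") -> "AffineTransform":
        f = np.broadcast_to(np.asarray(factors, dtype=float), (3,))
        return cls(np.diag(f), np.zeros(3), direction)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.linear.T + self.offset

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.linear)
        parts = self.direction.split("->")
        direction = "->".join(reversed(parts)) if len(parts) == 2 else self.direction
        return AffineTransform(inv, -inv @ self.offset, direction)

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Return self o other (apply ``other`` first)."""
        return AffineTransform(
            self.linear @ other.linear,
            self.linear @ other.offset + self.offset,
            other.direction.split("->")[0] + "->" + self.direction.split("->")[-1],
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def apply_affine(
    vol: ScalarVolume | LabelVolume,
    t: AffineTransform,
    target: VoxelGrid,
    mode: Literal["nearest", "trilinear"] = "trilinear",
):
    """Resample ``vol`` onto ``target``, where ``t`` maps source world
    coordinates to target world coordinates.

    Each target voxel centre is pulled back through ``t.inverse()`` and the
    source is sampled there; out-of-bounds samples are 0.  Label volumes
    require nearest-neighbour interpolation.
    """
    is_label = isinstance(vol, LabelVolume)
    if is_label and mode != "nearest":
        raise UsageError("LabelVolume resampling requires mode='nearest'")
    if mode not in ("nearest", "trilinear"):
        raise UsageError(f"unknown mode {mode!r}")

    inv = t.inverse()
    tgt_world = target.index_grid_world()  # (*shape, 3)
    src_world = inv(tgt_world.reshape(-1, 3))
    src_idx = vol.grid.voxel_from_world(src_world).T  # (3, n)

    data = vol.labels if is_label else vol.values
    order = 0 if mode == "nearest" else 1
    out = ndimage.map_coordinates(
        data.astype(float), src_idx, order=order, mode="grid-constant", cval=0.0
    ).reshape(target.shape)

    if is_label:
        out = np.round(out).astype(data.dtype)
        return LabelVolume(target, out, vol.region_table)
    return ScalarVolume(target, out)


def resample(
    vol: ScalarVolume,
    factor: int,
    reducer: Literal["mean", "nearest"] = "mean",
) -> ScalarVolume:
    """Integer downsampling; ``mean`` averages factor^3 blocks (partial edge
    blocks average only existing voxels), ``nearest`` picks block corners."""
    factor = int(factor)
    if factor < 1:
        raise UsageError("factor must be >= 1")
    if factor == 1:
        return vol.copy()
    out_shape = tuple(int(np.ceil(s / factor)) for s in vol.grid.shape)
    new_grid = VoxelGrid(
        out_shape,
        tuple(s * factor for s in vol.grid.spacing),
        vol.grid.origin,
        vol.grid.axis_order,
    )
    if reducer == "nearest":
        out = vol.values[::factor, ::factor, ::factor].copy()
    elif reducer == "mean":
        pad = [(0, o * factor - s) for o, s in zip(out_shape, vol.grid.shape)]
        padded = np.pad(vol.values, pad, constant_values=np.nan)
        blocks = padded.reshape(
            out_shape[0], factor, out_shape[1], factor, out_shape[2], factor
        )
        with np.errstate(invalid="ignore"):
            out = np.nanmean(blocks, axis=(1, 3, 5))
    else:
        raise UsageError(f"unknown reducer {reducer!r}")
    return ScalarVolume(new_grid, out)


def rescale_display_range(vol: ScalarVolume, lo: float, hi: float) -> ScalarVolume:
    """Linearly rescale [lo, hi] -> [0, 1] with clamping at both ends."""
    if hi <= lo:
        raise UsageError(f"hi ({hi}) must exceed lo ({lo})")
    out = np.clip((vol.values - lo) / (hi - lo), 0.0, 1.0)
    return ScalarVolume(vol.grid, out)
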