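"""Synthetic bilateral atlases and lesion/control cohorts with ground truth.

The generator builds a toy brain (ellipsoidal mask, mirror-symmetric labelled
nuclei and projection regions), then renders per-sample volumes: Poisson-placed
cell somata as Gaussian blobs, curvilinear fibres as momentum random walks,
a smooth low-frequency background and additive Gaussian noise.  A unilateral
"lesion" multiplies cell densities and fibre fills by per-(region, side)
factors; focal compensation factors (>1) can be applied to fibre fills.
Ground truth (cell centres, fibre masks, realised counts/fills, applied
factors) is recorded before noise so every downstream stage can be validated.

The ipsilateral (lesioned) side is the right hemisphere (x >= shape_x / 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume_core import (
    LabelVolume,
    RegionTable,
    ScalarVolume,
    UsageError,
    VoxelGrid,
)

Side = Literal["ipsi", "contra"]
Treatment = Literal["lesion", "vehicle"]


class AtlasSpecError(ValueError):
    """Raised for geometrically invalid toy-atlas specifications."""


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionSpec:
    """One ellipsoidal region; bilateral regions are mirrored across x."""

    label_id: int
    name: str
    cell_group: str = "none"
    excluded: bool = False
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)  # voxel coords, right side
    radii: tuple[float, float, float] = (3.0, 3.0, 3.0)  # voxels
    bilateral: bool = True


@dataclass(frozen=True)
class ToyAtlasSpec:
    shape: tuple[int, int, int] = (64, 48, 48)
    spacing: tuple[float, float, float] = (100.0, 100.0, 100.0)  # um
    brain_radii: tuple[float, float, float] = (30.0, 22.0, 22.0)  # voxels
    regions: tuple[RegionSpec, ...] = ()
    brain_label: int | None = 9  # label for brain voxels outside any region
    seed: int = 0


@dataclass(frozen=True)
class CohortSpec:
    """Cohort design: group sizes, densities, fills, effects and noise."""

    n_lesion: int = 10
    n_vehicle: int = 8
    cell_density: dict = field(default_factory=dict)  # label -> cells/mm^3
    fiber_fill: dict = field(default_factory=dict)  # label -> fraction in [0,1]
    lesion_cell_effects: dict = field(default_factory=dict)  # label -> (ipsi, contra)
    lesion_fiber_effects: dict = field(default_factory=dict)  # label -> (ipsi, contra)
    compensation_effects: dict = field(default_factory=dict)  # label -> (ipsi, contra), > 1
    noise_sd: float = 2.0
    background_amplitude: float = 4.0
    psf_sigma: float = 50.0  # um; cell blob sigma
    min_separation: float = 3.0  # voxels; soft repulsion between cell centres
    cell_amplitude: float = 100.0
    fiber_amplitude: float = 80.0
    fiber_persistence: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.cell_density.values()):
            raise UsageError("cell densities must be >= 0")
        if any(not (0.0 <= f <= 1.0) for f in self.fiber_fill.values()):
            raise UsageError("fiber fills must lie in [0, 1]")
        for effects in (
            self.lesion_cell_effects,
            self.lesion_fiber_effects,
            self.compensation_effects,
        ):
            for pair in effects.values():
                if any(f < 0 for f in pair):
                    raise UsageError("effect factors must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated sample."""

    cells: pd.DataFrame  # columns x, y, z (voxel coords), label, side
    fiber_mask: np.ndarray  # bool, voxels rendered as fibre
    signal_mask: np.ndarray  # bool, cells-plus-fibres ground-truth segmentation
    summary: pd.DataFrame  # per (label, side): counts, fills, applied factors
    warnings: list = field(default_factory=list)

    def cell_count(self, label: int, side: Side) -> int:
        sel = (self.cells["label"] == label) & (self.cells["side"] == side)
        return int(sel.sum())


@dataclass
class SampleRecord:
    sample_id: str
    treatment: Treatment
    volume: ScalarVolume
    truth: SyntheticTruth
    seed: int


# ---------------------------------------------------------------------------
# atlas construction
# ---------------------------------------------------------------------------

def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    idx = np.indices(shape, dtype=float)
    d2 = sum(
        ((idx[a] - center[a]) / radii[a]) ** 2 for a in range(3)
    )
    return d2 <= 1.0


def make_toy_atlas(spec: ToyAtlasSpec) -> LabelVolume:
    """Build a mirror-symmetric labelled toy brain from ``spec``.

    Bilateral regions are constructed on the right side and mirrored by an
    exact x-index flip, so symmetry holds voxel-for-voxel.
    """
    shape = tuple(int(s) for s in spec.shape)
    brain_center = tuple((s - 1) / 2.0 for s in shape)
    brain = _ellipsoid_mask(shape, brain_center, spec.brain_radii)

    labels = np.zeros(shape, dtype=np.int32)
    masks: dict[int, np.ndarray] = {}
    for region in spec.regions:
        right = _ellipsoid_mask(shape, region.center, region.radii)
        mask = right | right[::-1] if region.bilateral else right
        if np.any(mask & ~brain):
            raise AtlasSpecError(
                f"region {region.label_id} ({region.name}) leaves the brain mask"
            )
        masks[region.label_id] = mask

    colliding = []
    ids = sorted(masks)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if np.any(masks[a] & masks[b]):
                colliding.append((a, b))
    if colliding:
        raise AtlasSpecError(f"overlapping region ellipsoids: {colliding}")

    for label_id, mask in masks.items():
        labels[mask] = label_id
    if spec.brain_label is not None:
        if spec.brain_label in masks:
            raise AtlasSpecError("brain_label collides with a region label")
        labels[brain & (labels == 0)] = spec.brain_label

    rows = [
        dict(
            label_id=r.label_id,
            name=r.name,
            parent_id=None,
            cell_group=r.cell_group,
            excluded=r.excluded,
        )
        for r in spec.regions
    ]
    if spec.brain_label is not None:
        rows.append(
            dict(
                label_id=spec.brain_label,
                name="BrainRest",
                parent_id=None,
                cell_group="none",
                excluded=False,
            )
        )
    if not rows:
        table = RegionTable(pd.DataFrame(columns=list(RegionTable.COLUMNS)))
    else:
        table = RegionTable.from_rows(rows)
    grid = VoxelGrid(shape, spec.spacing)
    vol = LabelVolume(grid, labels, table)
    vol.brain_mask = brain  # type: ignore[attr-defined]
    return vol


# canonical toy layout: a dopaminergic nucleus, a noradrenergic nucleus,
# a projection region receiving fibres, and an excluded ventricle analogue
DEFAULT_REGIONS = (
    RegionSpec(1, "NucA", "dopaminergic", False, (45.0, 16.0, 18.0), (6.0, 7.0, 8.0)),
    RegionSpec(2, "NucB", "noradrenergic", False, (40.0, 8.0, 26.0), (3.0, 3.0, 4.0)),
    RegionSpec(3, "Proj", "none", False, (44.0, 33.0, 25.0), (7.0, 8.0, 8.0)),
    RegionSpec(4, "Vent", "none", True, (34.0, 24.0, 30.0), (2.0, 3.0, 3.0)),
)


def default_atlas_spec(shape=(64, 48, 48), seed: int = 0) -> ToyAtlasSpec:
    """Scale the canonical region layout to ``shape`` (reference 64x48x48)."""
    ref = np.array([64.0, 48.0, 48.0])
    scale = np.asarray(shape, dtype=float) / ref
    regions = tuple(
        RegionSpec(
            r.label_id,
            r.name,
            r.cell_group,
            r.excluded,
            tuple(np.asarray(r.center) * scale),
            tuple(np.maximum(np.asarray(r.radii) * scale, 1.5)),
            r.bilateral,
        )
        for r in DEFAULT_REGIONS
    )
    brain_radii = tuple(np.array([30.0, 22.0, 22.0]) * scale)
    return ToyAtlasSpec(
        shape=tuple(shape),
        spacing=(100.0,) * 3,
        brain_radii=brain_radii,
        regions=regions,
        seed=seed,
    )


def default_cohort_spec(**overrides) -> CohortSpec:
    base = dict(
        n_lesion=8,
        n_vehicle=8,
        cell_density={1: 30.0, 2: 40.0},
        fiber_fill={3: 0.12},
        lesion_cell_effects={1: (0.5, 1.0)},
        lesion_fiber_effects={3: (0.5, 0.8)},
        compensation_effects={},
        noise_sd=2.0,
        background_amplitude=4.0,
        psf_sigma=50.0,
        cell_amplitude=100.0,
        fiber_amplitude=80.0,
        seed=0,
    )
    base.update(overrides)
    return CohortSpec(**base)


# ---------------------------------------------------------------------------
# sample rendering
# ---------------------------------------------------------------------------

def _side_masks(atlas: LabelVolume) -> dict[Side, np.ndarray]:
    mid = atlas.grid.shape[0] // 2
    x = np.arange(atlas.grid.shape[0])[:, None, None]
    ipsi = np.broadcast_to(x >= mid, atlas.grid.shape)
    return {"ipsi": ipsi, "contra": ~ipsi}


def _gaussian_stamp(sigma_vox: float) -> np.ndarray:
    r = max(1, int(np.ceil(3 * sigma_vox)))
    ax = np.arange(-r, r + 1, dtype=float)
    g1 = np.exp(-0.5 * (ax / sigma_vox) ** 2)
    return g1[:, None, None] * g1[None, :, None] * g1[None, None, :]


def _stamp_at(field: np.ndarray, stamp: np.ndarray, center: np.ndarray, amp: float):
    r = stamp.shape[0] // 2
    c = np.round(center).astype(int)
    lo = np.maximum(c - r, 0)
    hi = np.minimum(c + r + 1, np.asarray(field.shape))
    slo = lo - (c - r)
    shi = stamp.shape[0] - ((c + r + 1) - hi)
    field[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += (
        amp * stamp[slo[0] : shi[0], slo[1] : shi[1], slo[2] : shi[2]]
    )


def _random_walk_fill(
    mask: np.ndarray,
    target_voxels: int,
    rng: np.random.Generator,
    persistence: float,
    max_steps: int = 2_000_000,
) -> np.ndarray:
    """Fill ``mask`` with 1-voxel-wide momentum random walks until
    ``target_voxels`` distinct voxels are visited."""
    out = np.zeros_like(mask, dtype=bool)
    if target_voxels <= 0:
        return out
    candidates = np.argwhere(mask)
    filled = 0
    pos = candidates[rng.integers(len(candidates))].astype(float)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    for _ in range(max_steps):
        v = tuple(np.round(pos).astype(int))
        inside = (
            all(0 <= v[a] < mask.shape[a] for a in range(3)) and mask[v]
        )
        if inside:
            if not out[v]:
                out[v] = True
                filled += 1
                if filled >= target_voxels:
                    break
            step = persistence * direction + (1 - persistence) * rng.normal(size=3)
            norm = np.linalg.norm(step)
            direction = step / norm if norm > 0 else direction
            pos = pos + direction
        else:
            # walked out of the region: restart a new fibre
            pos = candidates[rng.integers(len(candidates))].astype(float)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
    return out


def _smooth_background(shape, amplitude, rng) -> np.ndarray:
    if amplitude == 0:
        return np.zeros(shape)
    coarse_shape = tuple(max(2, s // 8) for s in shape)
    coarse = rng.normal(size=coarse_shape)
    zoom = [s / c for s, c in zip(shape, coarse_shape)]
    field = ndimage.zoom(coarse, zoom, order=3)[: shape[0], : shape[1], : shape[2]]
    pad = [(0, shape[a] - field.shape[a]) for a in range(3)]
    field = np.pad(field, pad, mode="edge")
    return amplitude * (field - field.min()) / max(np.ptp(field), 1e-12)


def _place_cells(
    voxels: np.ndarray,
    count: int,
    min_separation: float,
    rng: np.random.Generator,
    notes: list,
    label: int,
    side: str,
    max_tries: int = 50,
) -> np.ndarray:
    """Draw ``count`` jittered centres from ``voxels`` with soft repulsion:
    rejection-sample up to ``max_tries`` candidates per cell, then accept
    regardless (keeping the count Poisson-distributed)."""
    accepted: list[np.ndarray] = []
    crowded = 0
    for _ in range(count):
        candidate = None
        for _try in range(max_tries):
            c = voxels[rng.integers(len(voxels))] + rng.uniform(-0.5, 0.5, size=3)
            if not accepted or np.min(
                np.linalg.norm(np.asarray(accepted) - c, axis=1)
            ) >= min_separation:
                candidate = c
                break
        if candidate is None:
            candidate = voxels[rng.integers(len(voxels))] + rng.uniform(-0.5, 0.5, 3)
            crowded += 1
        accepted.append(candidate)
    if crowded:
        notes.append(
            f"{crowded} cell(s) placed closer than min_separation in label "
            f"{label} side {side} (region crowded)"
        )
    return np.asarray(accepted)


def _effect_factor(effects: dict, label: int, side: Side) -> float:
    pair = effects.get(label)
    if pair is None:
        return 1.0
    return float(pair[0] if side == "ipsi" else pair[1])


def simulate_sample(
    atlas: LabelVolume,
    cohort: CohortSpec,
    treatment: Treatment,
    sample_seed: int,
) -> tuple[ScalarVolume, SyntheticTruth]:
    """Render one sample volume and its ground truth.

    Cell counts per (region, side) are Poisson(density x volume x factor);
    fibres are momentum random walks filling the target fraction of each
    projection region; a smooth background and i.i.d. Gaussian noise are
    added last (truth is recorded before noise).
    """
    known = set(int(x) for x in atlas.region_table.label_ids)
    for label in list(cohort.cell_density) + list(cohort.fiber_fill):
        if label not in known:
            raise UsageError(f"cohort references unknown region label {label}")

    rng = np.random.default_rng(sample_seed)
    shape = atlas.grid.shape
    sides = _side_masks(atlas)
    voxvol = atlas.grid.voxel_volume_mm3
    sigma_vox = cohort.psf_sigma / float(np.mean(atlas.grid.spacing))
    stamp = _gaussian_stamp(sigma_vox)

    cell_field = np.zeros(shape)
    fiber_mask = np.zeros(shape, dtype=bool)
    cell_rows = []
    summary_rows = []
    notes: list[str] = []
    lesioned = treatment == "lesion"

    for label, density in sorted(cohort.cell_density.items()):
        region = atlas.labels == label
        for side in ("ipsi", "contra"):
            m = region & sides[side]
            nvox = int(m.sum())
            factor = _effect_factor(cohort.lesion_cell_effects, label, side) if lesioned else 1.0
            mean = density * nvox * voxvol * factor
            count = int(rng.poisson(mean)) if mean > 0 else 0
            voxels = np.argwhere(m)
            if count and len(voxels):
                centers = _place_cells(
                    voxels, count, cohort.min_separation, rng, notes, label, side
                )
                for c in centers:
                    _stamp_at(cell_field, stamp, c, cohort.cell_amplitude)
                    cell_rows.append(
                        dict(x=c[0], y=c[1], z=c[2], label=label, side=side)
                    )
            summary_rows.append(
                dict(
                    label=label,
                    side=side,
                    measure="cell",
                    true_count=count if len(voxels) else 0,
                    true_fill=np.nan,
                    factor=factor,
                    region_voxels=nvox,
                )
            )

    for label, fill in sorted(cohort.fiber_fill.items()):
        region = atlas.labels == label
        for side in ("ipsi", "contra"):
            m = region & sides[side]
            nvox = int(m.sum())
            factor = 1.0
            if lesioned:
                factor = _effect_factor(cohort.lesion_fiber_effects, label, side)
                factor *= _effect_factor(cohort.compensation_effects, label, side)
            target_fill = fill * factor
            if target_fill > 1.0:
                notes.append(
                    f"fiber fill clipped to 1.0 for label {label} side {side} "
                    f"(requested {target_fill:.3f})"
                )
                target_fill = 1.0
            target = int(round(target_fill * nvox))
            walked = _random_walk_fill(m, target, rng, cohort.fiber_persistence)
            fiber_mask |= walked
            summary_rows.append(
                dict(
                    label=label,
                    side=side,
                    measure="fiber",
                    true_count=np.nan,
                    true_fill=walked.sum() / nvox if nvox else 0.0,
                    factor=factor,
                    region_voxels=nvox,
                )
            )

    signal = cell_field + cohort.fiber_amplitude * fiber_mask
    signal_mask = (cell_field >= 0.5 * cohort.cell_amplitude) | fiber_mask
    background = _smooth_background(shape, cohort.background_amplitude, rng)
    noise = rng.normal(0.0, cohort.noise_sd, size=shape) if cohort.noise_sd > 0 else 0.0
    values = signal + background + noise

    cells = pd.DataFrame(cell_rows, columns=["x", "y", "z", "label", "side"])
    truth = SyntheticTruth(
        cells=cells,
        fiber_mask=fiber_mask,
        signal_mask=signal_mask,
        summary=pd.DataFrame(summary_rows),
        warnings=notes,
    )
    return ScalarVolume(atlas.grid, values), truth


def make_cohort(atlas: LabelVolume, cohort: CohortSpec) -> list[SampleRecord]:
    """Simulate the full cohort with per-sample seeds derived from the
    cohort seed."""
    if cohort.n_lesion < 2 or cohort.n_vehicle < 2:
        raise UsageError("need at least 2 samples per group for validation t-tests")
    n = cohort.n_lesion + cohort.n_vehicle
    children = np.random.SeedSequence(cohort.seed).spawn(n)
    records = []
    plan = [("lesion", i) for i in range(cohort.n_lesion)] + [
        ("vehicle", i) for i in range(cohort.n_vehicle)
    ]
    for (treatment, i), child in zip(plan, children):
        seed = int(child.generate_state(1)[0])
        vol, truth = simulate_sample(atlas, cohort, treatment, seed)
        records.append(
            SampleRecord(f"{treatment}_{i:02d}", treatment, vol, truth, seed)
        )
    return records


def cohort_manifest(records: Sequence[SampleRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [dict(sample_id=r.sample_id, treatment=r.treatment, seed=r.seed) for r in records]
    )
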