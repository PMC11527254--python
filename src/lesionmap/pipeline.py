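"""End-to-end orchestration: simulate -> preprocess -> voxelwise -> fdr ->
validate -> report.

Each stage exists both as a pure in-memory function and as a file-based
stage operating in a working directory (so stages are independently
invocable and a resumed run equals a full run).  All randomness derives
from the single config seed; outputs are byte-reproducible.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as lio
from .cluster_validation import (
    count_cells,
    fiber_density,
    partition_cluster,
    segment_signal,
    validate_cluster,
    warp_cluster,
)
from .fdr_clustering import (
    DEFAULT_Q_GRID,
    ClusterSet,
    FDRResult,
    cluster_composition,
    select_q,
    split_by_direction,
)
from .preprocess import (
    exclusion_mask,
    flip_left_to_right,
    gaussian_smooth,
    rolling_ball_subtract,
)
from .synthetic_data import (
    CohortSpec,
    SampleRecord,
    cohort_manifest,
    default_atlas_spec,
    default_cohort_spec,
    make_cohort,
    make_toy_atlas,
)
from .volume_core import AffineTransform, LabelVolume, ScalarVolume, UsageError
from .voxelwise_stats import (
    CONTRAST_NAMES,
    ObservationSet,
    StatMap,
    permutation_fmap,
    posthoc_contrasts,
)

log = logging.getLogger("lesionmap")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "atlas": {"shape": [64, 48, 48]},
    "cohort": {},  # overrides for default_cohort_spec
    # toy volumes use 100 um voxels; 0.25 mm sigma = 2.5 voxels (the paper-scale
    # default of 0.05 mm is appropriate for 25 um atlas resolution)
    "preprocess": {
        "rolling_ball_radius": 6,
        "smooth_sigma_mm": 0.25,
        "apply_rolling_ball": True,
    },
    "voxelwise": {"n_perm": 1000, "alpha": 0.05, "gating": "union"},
    "fdr": {"q_grid": list(DEFAULT_Q_GRID), "min_cluster": 100, "connectivity": 26},
    "validation": {
        "method": "otsu",
        "quantile": 0.99,
        "min_size": 1,
        "alpha": 0.05,
    },
}

SMOKE_CONFIG: dict = {
    "seed": 7,
    "atlas": {"shape": [32, 32, 32]},
    "cohort": {"n_lesion": 3, "n_vehicle": 3},
    "preprocess": {"rolling_ball_radius": 4, "smooth_sigma_mm": 0.05,
                   "apply_rolling_ball": True},
    "voxelwise": {"n_perm": 200, "alpha": 0.05, "gating": "union"},
    "fdr": {"q_grid": list(DEFAULT_Q_GRID), "min_cluster": 50, "connectivity": 26},
    "validation": {"method": "otsu", "quantile": 0.99,
                   "min_size": 1, "alpha": 0.05},
}


def merge_config(overrides: Optional[dict] = None) -> dict:
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    for key, val in (overrides or {}).items():
        if key not in cfg:
            raise UsageError(f"unknown config section: {key}")
        if isinstance(val, dict):
            cfg[key] = {**cfg[key], **val}
        else:
            cfg[key] = val
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()


# ---------------------------------------------------------------------------
# in-memory stages
# ---------------------------------------------------------------------------

def preprocess_sample(
    vol: ScalarVolume,
    radius: int = 6,
    sigma_mm: float = 0.05,
    apply_rolling_ball: bool = True,
) -> ScalarVolume:
    out = rolling_ball_subtract(vol, radius) if apply_rolling_ball else vol
    return gaussian_smooth(out, sigma_mm)


def hemisphere_mask(atlas: LabelVolume) -> np.ndarray:
    """Analysis mask: non-excluded labelled voxels of the right (ipsilateral)
    hemisphere; left hemispheres enter as flipped observations."""
    mask = exclusion_mask(atlas)
    mid = atlas.grid.shape[0] // 2
    mask[:mid] = False
    return mask


def build_observations(
    preprocessed: list[tuple[str, str, ScalarVolume]],
    mask: np.ndarray,
) -> ObservationSet:
    """Expand (sample_id, treatment, volume) into ipsi + flipped-contra
    observations on the hemisphere mask."""
    volumes = []
    for sample_id, treatment, vol in preprocessed:
        volumes.append((sample_id, treatment, "ipsi", vol))
        volumes.append((sample_id, treatment, "contra", flip_left_to_right(vol)))
    return ObservationSet.from_volumes(volumes, mask)


def run_voxelwise(
    obs: ObservationSet,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    gating: str = "union",
) -> tuple[dict[str, StatMap], dict[str, StatMap]]:
    anova = {}
    for i, effect in enumerate(("side", "treatment", "interaction")):
        t0 = time.perf_counter()
        anova[effect] = permutation_fmap(obs, effect, n_perm=n_perm, seed=seed + i)
        log.info("F_%s p-map: %.1fs", effect, time.perf_counter() - t0)
    posthoc = posthoc_contrasts(
        obs, anova, alpha=alpha, n_perm=n_perm, seed=seed + 100, gating=gating
    )
    return anova, posthoc


def run_fdr(
    posthoc: dict[str, StatMap],
    q_grid=DEFAULT_Q_GRID,
    min_cluster: int = 100,
    connectivity: int = 26,
) -> dict[str, dict]:
    """Cluster-constrained FDR per contrast, with direction splitting."""
    out = {}
    for name, pmap in posthoc.items():
        gate = getattr(pmap, "gate", None)
        res = select_q(
            pmap, q_grid=q_grid, min_cluster=min_cluster,
            connectivity=connectivity, contrast=name, restrict=gate,
        )
        directed = (
            split_by_direction(res.clusters, _sign_volume(pmap), min_cluster)
            if res.has_signal
            else res.clusters
        )
        log.info(
            "contrast %s: q=%s, %d significant voxels, %d directed clusters",
            name, res.q, res.n_significant, directed.n_clusters,
        )
        out[name] = {"fdr": res, "clusters": directed}
    return out


def _sign_volume(pmap: StatMap) -> np.ndarray:
    out = np.zeros(pmap.grid.shape)
    out[pmap.mask] = pmap.sign if pmap.sign is not None else 0
    return out


CONTRAST_GROUPS = {
    # contrast -> (group A (treatment, flip?), group B (treatment, flip?));
    # flip=True measures the contralateral side via the mirrored cluster mask
    "lesion_ipsi_vs_contra": (("lesion", False), ("lesion", True)),
    "vehicle_ipsi_vs_contra": (("vehicle", False), ("vehicle", True)),
    "lesion_vs_vehicle_ipsi": (("lesion", False), ("vehicle", False)),
    "lesion_vs_vehicle_contra": (("lesion", True), ("vehicle", True)),
}


def run_validation(
    fdr_results: dict[str, dict],
    records: list[SampleRecord],
    atlas: LabelVolume,
    method: str = "quantile_threshold",
    quantile: float = 0.99,
    min_size: int = 2,
    alpha: float = 0.05,
    atlas_to_tissue: Optional[AffineTransform] = None,
    tissue_grid=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Measure per-sample cell and fiber densities inside each cluster and
    run the unpaired validation t-tests.

    Clusters live in (right-hemisphere) atlas space; the contralateral value
    of a sample is measured through the mirrored cluster mask.  Segmentations
    are computed on the raw volumes.
    """
    atlas_to_tissue = atlas_to_tissue or AffineTransform.identity("atlas->tissue")
    tissue_grid = tissue_grid or records[0].volume.grid
    cellgroup = atlas.mask_of(atlas.region_table.cell_group_labels())

    segs = {
        r.sample_id: segment_signal(
            r.volume, method=method, quantile=quantile, min_size=min_size
        )
        for r in records
    }
    by_treatment = {
        "lesion": [r for r in records if r.treatment == "lesion"],
        "vehicle": [r for r in records if r.treatment == "vehicle"],
    }

    density_rows = []
    validation_rows = []
    for contrast, payload in fdr_results.items():
        clusters: ClusterSet = payload["clusters"]
        spec_a, spec_b = CONTRAST_GROUPS[contrast]
        for _, crow in clusters.table.iterrows():
            cid = int(crow["cluster_id"])
            cmask = clusters.mask_of(cid)
            cell_part, fiber_part = partition_cluster(cmask, cellgroup)
            parts = []
            if cell_part.sum() > 0:
                parts.append(("cell_density", cell_part))
            if fiber_part.sum() > 0:
                parts.append(("fiber_density", fiber_part))

            any_valid = False
            for measure, part in parts:
                tissue_mask = warp_cluster(part, atlas.grid, atlas_to_tissue, tissue_grid)
                if tissue_mask.sum() == 0:
                    continue
                mirrored = tissue_mask[::-1]
                values = {}
                group_specs = [spec_a] + ([spec_b] if spec_b != spec_a else [])
                for treatment, flip in group_specs:
                    mask = mirrored if flip else tissue_mask
                    vals = []
                    for r in by_treatment[treatment]:
                        if measure == "cell_density":
                            _, v = count_cells(segs[r.sample_id], mask, tissue_grid)
                        else:
                            v = fiber_density(segs[r.sample_id], mask)
                        vals.append(v)
                        density_rows.append(
                            dict(
                                contrast=contrast,
                                cluster_id=cid,
                                sample_id=r.sample_id,
                                treatment=treatment,
                                side="contra" if flip else "ipsi",
                                measure=measure,
                                value=v,
                                cluster_volume_mm3=tissue_mask.sum()
                                * tissue_grid.voxel_volume_mm3,
                            )
                        )
                    values[(treatment, flip)] = vals
                vres = validate_cluster(
                    values[spec_a], values[spec_b], alpha=alpha,
                    cluster_id=cid, measure=measure,
                )
                any_valid |= vres.valid
                validation_rows.append(
                    dict(
                        contrast=contrast,
                        cluster_id=cid,
                        measure=measure,
                        n_voxels=int(part.sum()),
                        t=vres.t,
                        p=vres.p,
                        valid=vres.valid,
                        direction=vres.direction,
                        n_a=vres.n_a,
                        n_b=vres.n_b,
                    )
                )
            log.info(
                "contrast %s cluster %d: valid=%s", contrast, cid, any_valid
            )

    dens_cols = ["contrast", "cluster_id", "sample_id", "treatment", "side",
                 "measure", "value", "cluster_volume_mm3"]
    val_cols = ["contrast", "cluster_id", "measure", "n_voxels", "t", "p",
                "valid", "direction", "n_a", "n_b"]
    return (
        pd.DataFrame(density_rows, columns=dens_cols),
        pd.DataFrame(validation_rows, columns=val_cols),
    )


# ---------------------------------------------------------------------------
# whole-cohort driver
# ---------------------------------------------------------------------------

class PipelineResult:
    def __init__(self):
        self.atlas: Optional[LabelVolume] = None
        self.records: list[SampleRecord] = []
        self.mask: Optional[np.ndarray] = None
        self.obs: Optional[ObservationSet] = None
        self.anova: dict[str, StatMap] = {}
        self.posthoc: dict[str, StatMap] = {}
        self.fdr: dict[str, dict] = {}
        self.densities: Optional[pd.DataFrame] = None
        self.validation: Optional[pd.DataFrame] = None
        self.report: dict = {}


def analyze_cohort(
    atlas: LabelVolume,
    records: list[SampleRecord],
    config: Optional[dict] = None,
) -> PipelineResult:
    """Run preprocess -> voxelwise -> fdr -> validation on simulated records."""
    cfg = merge_config(config)
    res = PipelineResult()
    res.atlas = atlas
    res.records = records

    pre_cfg = cfg["preprocess"]
    preprocessed = [
        (
            r.sample_id,
            r.treatment,
            preprocess_sample(
                r.volume,
                radius=pre_cfg["rolling_ball_radius"],
                sigma_mm=pre_cfg["smooth_sigma_mm"],
                apply_rolling_ball=pre_cfg["apply_rolling_ball"],
            ),
        )
        for r in records
    ]
    res.mask = hemisphere_mask(atlas)
    res.obs = build_observations(preprocessed, res.mask)

    vw = cfg["voxelwise"]
    res.anova, res.posthoc = run_voxelwise(
        res.obs, n_perm=vw["n_perm"], alpha=vw["alpha"],
        seed=cfg["seed"] + 1000, gating=vw["gating"],
    )
    fd = cfg["fdr"]
    res.fdr = run_fdr(
        res.posthoc, q_grid=fd["q_grid"], min_cluster=fd["min_cluster"],
        connectivity=fd["connectivity"],
    )
    val = cfg["validation"]
    res.densities, res.validation = run_validation(
        res.fdr, records, atlas,
        method=val["method"], quantile=val["quantile"],
        min_size=val["min_size"], alpha=val["alpha"],
    )
    res.report = build_report(cfg, res)
    return res


def build_report(cfg: dict, res: PipelineResult) -> dict:
    contrasts = {}
    for name, payload in res.fdr.items():
        fdr: FDRResult = payload["fdr"]
        clusters: ClusterSet = payload["clusters"]
        val = res.validation[res.validation["contrast"] == name]
        contrasts[name] = dict(
            q=fdr.q,
            p_threshold=fdr.p_threshold,
            m=fdr.m,
            n_significant=fdr.n_significant,
            n_clusters=clusters.n_clusters,
            cluster_sizes=[int(s) for s in clusters.table["n_voxels"]],
            n_valid_clusters=int(
                val.groupby("cluster_id")["valid"].any().sum()
            ) if len(val) else 0,
        )
    return dict(
        config_hash=config_hash(cfg),
        seed=cfg["seed"],
        n_mask_voxels=int(res.mask.sum()) if res.mask is not None else 0,
        contrasts=contrasts,
    )


# ---------------------------------------------------------------------------
# file-based stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: dict, workdir: Path) -> None:
    workdir = Path(workdir)
    (workdir / "samples").mkdir(parents=True, exist_ok=True)
    atlas_spec = default_atlas_spec(tuple(cfg["atlas"]["shape"]), seed=cfg["seed"])
    atlas = make_toy_atlas(atlas_spec)
    cohort = default_cohort_spec(seed=cfg["seed"], **cfg["cohort"])
    records = make_cohort(atlas, cohort)

    lio.save_nifti(atlas, workdir / "atlas.nii")
    atlas.region_table.to_csv(workdir / "regions.csv")
    manifest = cohort_manifest(records)
    manifest["path"] = [f"samples/{r.sample_id}.nii" for r in records]
    manifest.to_csv(workdir / "manifest.csv", index=False)
    truth_frames = []
    for r in records:
        lio.save_nifti(r.volume, workdir / "samples" / f"{r.sample_id}.nii")
        lio.save_nifti(
            ScalarVolume(r.volume.grid, r.truth.signal_mask.astype(float)),
            workdir / "samples" / f"{r.sample_id}_truth_seg.nii",
        )
        t = r.truth.summary.copy()
        t.insert(0, "sample_id", r.sample_id)
        truth_frames.append(t)
    pd.concat(truth_frames, ignore_index=True).to_csv(
        workdir / "truth.csv", index=False
    )


def _load_atlas(workdir: Path) -> LabelVolume:
    from .volume_core import RegionTable

    table = RegionTable.from_csv(workdir / "regions.csv")
    return lio.load_label_nifti(workdir / "atlas.nii", table)


def stage_preprocess(cfg: dict, workdir: Path) -> None:
    workdir = Path(workdir)
    (workdir / "preproc").mkdir(exist_ok=True)
    manifest = pd.read_csv(workdir / "manifest.csv")
    pre = cfg["preprocess"]
    for row in manifest.itertuples():
        vol = lio.load_scalar_nifti(workdir / row.path)
        out = preprocess_sample(
            vol, radius=pre["rolling_ball_radius"],
            sigma_mm=pre["smooth_sigma_mm"],
            apply_rolling_ball=pre["apply_rolling_ball"],
        )
        lio.save_nifti(out, workdir / "preproc" / f"{row.sample_id}.nii")
    atlas = _load_atlas(workdir)
    mask = hemisphere_mask(atlas)
    lio.save_nifti(ScalarVolume(atlas.grid, mask.astype(float)), workdir / "mask.nii")


def _load_observations(workdir: Path) -> ObservationSet:
    manifest = pd.read_csv(workdir / "manifest.csv")
    mask = lio.load_scalar_nifti(workdir / "mask.nii").values > 0.5
    preprocessed = [
        (row.sample_id, row.treatment,
         lio.load_scalar_nifti(workdir / "preproc" / f"{row.sample_id}.nii"))
        for row in manifest.itertuples()
    ]
    return build_observations(preprocessed, mask)


def stage_voxelwise(cfg: dict, workdir: Path) -> None:
    workdir = Path(workdir)
    (workdir / "stats").mkdir(exist_ok=True)
    obs = _load_observations(workdir)
    vw = cfg["voxelwise"]
    anova, posthoc = run_voxelwise(
        obs, n_perm=vw["n_perm"], alpha=vw["alpha"],
        seed=cfg["seed"] + 1000, gating=vw["gating"],
    )
    for effect, sm in anova.items():
        _save_statmap(sm, workdir / "stats" / f"anova_{effect}")
    for name, sm in posthoc.items():
        _save_statmap(sm, workdir / "stats" / f"posthoc_{name}")
        gate = np.zeros(sm.grid.shape)
        gate[sm.mask] = getattr(sm, "gate").astype(float)
        lio.save_nifti(
            ScalarVolume(sm.grid, gate), workdir / "stats" / f"posthoc_{name}_gate.nii"
        )


def _save_statmap(sm: StatMap, prefix: Path) -> None:
    lio.save_nifti(ScalarVolume(sm.grid, sm.stat_volume()), Path(f"{prefix}_stat.nii"))
    lio.save_nifti(ScalarVolume(sm.grid, sm.p_volume()), Path(f"{prefix}_p.nii"))
    if sm.sign is not None:
        lio.save_nifti(ScalarVolume(sm.grid, sm.sign_volume()), Path(f"{prefix}_sign.nii"))
    with open(f"{prefix}.json", "w") as fh:
        json.dump(sm.metadata, fh, sort_keys=True, indent=1)


def _load_posthoc(workdir: Path, mask: np.ndarray, grid) -> dict[str, StatMap]:
    out = {}
    for name in CONTRAST_NAMES:
        prefix = workdir / "stats" / f"posthoc_{name}"
        p = lio.load_scalar_nifti(Path(f"{prefix}_p.nii")).values
        stat = lio.load_scalar_nifti(Path(f"{prefix}_stat.nii")).values
        sign = lio.load_scalar_nifti(Path(f"{prefix}_sign.nii")).values
        gate = lio.load_scalar_nifti(Path(f"{prefix}_gate.nii")).values
        with open(f"{prefix}.json") as fh:
            meta = json.load(fh)
        sm = StatMap(
            stat=stat[mask], p=p[mask], mask=mask, grid=grid,
            sign=sign[mask], metadata=meta,
        )
        sm.gate = gate[mask] > 0.5  # type: ignore[attr-defined]
        out[name] = sm
    return out


def stage_fdr(cfg: dict, workdir: Path) -> None:
    workdir = Path(workdir)
    (workdir / "clusters").mkdir(exist_ok=True)
    atlas = _load_atlas(workdir)
    mask = lio.load_scalar_nifti(workdir / "mask.nii").values > 0.5
    posthoc = _load_posthoc(workdir, mask, atlas.grid)
    fd = cfg["fdr"]
    results = run_fdr(
        posthoc, q_grid=fd["q_grid"], min_cluster=fd["min_cluster"],
        connectivity=fd["connectivity"],
    )
    tables = []
    comps = []
    for name, payload in results.items():
        clusters: ClusterSet = payload["clusters"]
        lio.save_nifti(
            ScalarVolume(clusters.grid, clusters.labels.astype(float)),
            workdir / "clusters" / f"{name}.nii",
        )
        t = clusters.table.drop(columns=["bbox"]).copy()
        t.insert(0, "contrast_name", name)
        fdr_res: FDRResult = payload["fdr"]
        t["m"] = fdr_res.m
        t["n_significant"] = fdr_res.n_significant
        tables.append(t)
        comp = cluster_composition(clusters, atlas)
        comp.insert(0, "contrast_name", name)
        comps.append(comp)
    pd.concat(tables, ignore_index=True).to_csv(workdir / "clusters.csv", index=False)
    pd.concat(comps, ignore_index=True).to_csv(workdir / "composition.csv", index=False)


def stage_validate(cfg: dict, workdir: Path) -> None:
    workdir = Path(workdir)
    atlas = _load_atlas(workdir)
    mask = lio.load_scalar_nifti(workdir / "mask.nii").values > 0.5
    posthoc = _load_posthoc(workdir, mask, atlas.grid)
    fd = cfg["fdr"]
    results = run_fdr(
        posthoc, q_grid=fd["q_grid"], min_cluster=fd["min_cluster"],
        connectivity=fd["connectivity"],
    )
    manifest = pd.read_csv(workdir / "manifest.csv")
    records = []
    for row in manifest.itertuples():
        vol = lio.load_scalar_nifti(workdir / row.path)
        records.append(SampleRecord(row.sample_id, row.treatment, vol, None, row.seed))
    val = cfg["validation"]
    densities, validation = run_validation(
        results, records, atlas,
        method=val["method"], quantile=val["quantile"],
        min_size=val["min_size"], alpha=val["alpha"],
    )
    densities.to_csv(workdir / "densities.csv", index=False)
    validation.to_csv(workdir / "validation.csv", index=False)

    contrasts = {}
    for name, payload in results.items():
        fdr_res: FDRResult = payload["fdr"]
        clusters: ClusterSet = payload["clusters"]
        v = validation[validation["contrast"] == name]
        contrasts[name] = dict(
            q=fdr_res.q,
            p_threshold=fdr_res.p_threshold,
            m=fdr_res.m,
            n_significant=fdr_res.n_significant,
            n_clusters=clusters.n_clusters,
            n_valid_clusters=int(v.groupby("cluster_id")["valid"].any().sum())
            if len(v) else 0,
        )
    report = dict(config_hash=config_hash(cfg), seed=cfg["seed"], contrasts=contrasts)
    with open(workdir / "report.json", "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=1)


STAGES = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "voxelwise": stage_voxelwise,
    "fdr": stage_fdr,
    "validate": stage_validate,
}


def run_pipeline(config: Optional[dict], workdir) -> dict:
    """Run every stage in order inside ``workdir``; returns the report."""
    cfg = merge_config(config)
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    with open(workdir / "config.json", "w") as fh:
        json.dump(cfg, fh, sort_keys=True, indent=1)
    for name in ("simulate", "preprocess", "voxelwise", "fdr", "validate"):
        t0 = time.perf_counter()
        STAGES[name](cfg, workdir)
        log.info("stage %s: %.1fs", name, time.perf_counter() - t0)
    with open(workdir / "report.json") as fh:
        return json.load(fh)
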