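"""Voxel-wise permutation inference for a 2x2 (side x treatment) design.

F statistics come from the cell-means linear model with effect coding;
for unbalanced designs the per-effect sums of squares are Type-III style
(full-model residual SS versus the model with that effect's column dropped).
Empirical p-values use the estimator (1 + b) / (1 + P), which includes the
identity permutation and therefore never returns 0.  When the number of
distinct relabellings (minus the identity) is at most ``n_perm``, the full
set is enumerated and the p-values are exact; otherwise relabellings are
drawn uniformly at random and the metadata records the estimator used.

Exchangeability: ipsi/contra observations from the same sample are treated
as freely exchangeable units; the factor(s) under test are permuted across
all observations (synchronised full-label permutation for the interaction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Literal, Optional, Sequence

import numpy as np

from .volume_core import GeometryError, ScalarVolume, UsageError, VoxelGrid

Effect = Literal["side", "treatment", "interaction"]

CONTRAST_NAMES = (
    "lesion_ipsi_vs_contra",
    "vehicle_ipsi_vs_contra",
    "lesion_vs_vehicle_ipsi",
    "lesion_vs_vehicle_contra",
)


# ---------------------------------------------------------------------------
# observations
# ---------------------------------------------------------------------------

@dataclass
class ObservationSet:
    """Flattened per-voxel observations for the 2x2 design.

    ``data`` is (n_obs, n_voxels) over the in-mask voxels of ``mask``.
    """

    data: np.ndarray
    side: np.ndarray  # "ipsi" / "contra" per observation
    treatment: np.ndarray  # "lesion" / "vehicle" per observation
    sample_ids: np.ndarray
    mask: np.ndarray  # boolean volume
    grid: VoxelGrid

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.side = np.asarray(self.side)
        self.treatment = np.asarray(self.treatment)
        self.sample_ids = np.asarray(self.sample_ids)
        n = self.data.shape[0]
        if not (len(self.side) == len(self.treatment) == len(self.sample_ids) == n):
            raise UsageError("observation annotations must match data rows")
        if self.data.shape[1] != int(self.mask.sum()):
            raise GeometryError("data columns must equal in-mask voxel count")
        for s in np.unique(self.sample_ids):
            sides = set(self.side[self.sample_ids == s])
            if sides != {"ipsi", "contra"}:
                raise UsageError(
                    f"sample {s} must contribute exactly one ipsi and one contra observation"
                )

    @classmethod
    def from_volumes(
        cls,
        volumes: Sequence[tuple[str, str, str, ScalarVolume]],
        mask: np.ndarray,
    ) -> "ObservationSet":
        """Build from (sample_id, treatment, side, volume) tuples sharing a grid."""
        grid = volumes[0][3].grid
        rows, sides, treats, ids = [], [], [], []
        for sample_id, treatment, side, vol in volumes:
            if vol.grid != grid:
                raise GeometryError("all observation volumes must share one grid")
            rows.append(vol.values[mask])
            sides.append(side)
            treats.append(treatment)
            ids.append(sample_id)
        return cls(np.array(rows), np.array(sides), np.array(treats), np.array(ids), mask, grid)

    def n_per_cell(self) -> dict[tuple[str, str], int]:
        out = {}
        for s in ("ipsi", "contra"):
            for t in ("lesion", "vehicle"):
                out[(s, t)] = int(np.sum((self.side == s) & (self.treatment == t)))
        return out

    def unflatten(self, flat: np.ndarray, fill: float = 0.0) -> np.ndarray:
        out = np.full(self.grid.shape, fill, dtype=float)
        out[self.mask] = flat
        return out


@dataclass
class StatMap:
    """A statistic map with its empirical p-values on a common mask."""

    stat: np.ndarray  # flattened over mask voxels
    p: np.ndarray  # flattened, in (0, 1]
    mask: np.ndarray
    grid: VoxelGrid
    sign: Optional[np.ndarray] = None  # -1/0/+1, t-maps only
    metadata: dict = field(default_factory=dict)

    def p_volume(self, fill: float = 1.0) -> np.ndarray:
        out = np.full(self.grid.shape, fill)
        out[self.mask] = self.p
        return out

    def stat_volume(self, fill: float = 0.0) -> np.ndarray:
        out = np.full(self.grid.shape, fill)
        out[self.mask] = self.stat
        return out

    def sign_volume(self) -> np.ndarray:
        out = np.zeros(self.grid.shape)
        if self.sign is not None:
            out[self.mask] = self.sign
        return out


# ---------------------------------------------------------------------------
# F statistics
# ---------------------------------------------------------------------------

def _design_columns(side_pm: np.ndarray, treat_pm: np.ndarray) -> np.ndarray:
    """Effect-coded design: intercept, side, treatment, interaction."""
    return np.column_stack(
        [np.ones_like(side_pm), side_pm, treat_pm, side_pm * treat_pm]
    )


def _proj_ss(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Sum of squares of the projection of each Y column onto col(X)."""
    q, _ = np.linalg.qr(X)
    a = q.T @ Y
    return np.einsum("ij,ij->j", a, a)


def _codes(values: np.ndarray, positive: str) -> np.ndarray:
    return np.where(values == positive, 1.0, -1.0)


def _f_from_labels(
    Y: np.ndarray,
    side_pm: np.ndarray,
    treat_pm: np.ndarray,
    tss: Optional[np.ndarray] = None,
) -> dict[str, np.ndarray]:
    """Type-III style F statistics via projection sums of squares."""
    n = Y.shape[0]
    df_resid = n - 4
    if df_resid <= 0:
        raise UsageError("need more than 4 observations for the 2x2 model")
    if tss is None:
        tss = np.einsum("ij,ij->j", Y, Y)
    X_full = _design_columns(side_pm, treat_pm)
    ss_full = _proj_ss(X_full, Y)
    rss_full = np.maximum(tss - ss_full, 0.0)
    scale = max(float(tss.max(initial=0.0)), 1.0)
    degenerate = rss_full <= 1e-12 * scale
    out = {}
    for name, col in (("side", 1), ("treatment", 2), ("interaction", 3)):
        num = np.maximum(ss_full - _proj_ss(np.delete(X_full, col, axis=1), Y), 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = num / (rss_full / df_resid)
        f = np.where(degenerate, np.where(num > 1e-12 * scale, np.inf, 0.0), f)
        out[name] = np.maximum(f, 0.0)
    return out


def fstats_2x2(obs: ObservationSet) -> dict[str, ScalarVolume]:
    """Classical two-way ANOVA F volumes for side, treatment, interaction."""
    for cell, count in obs.n_per_cell().items():
        if count < 2:
            raise UsageError(f"design cell {cell} has fewer than 2 observations")
    side_pm = _codes(obs.side, "ipsi")
    treat_pm = _codes(obs.treatment, "lesion")
    fs = _f_from_labels(obs.data, side_pm, treat_pm)
    return {
        name: ScalarVolume(obs.grid, obs.unflatten(np.nan_to_num(f, posinf=1e30)))
        for name, f in fs.items()
    }


# ---------------------------------------------------------------------------
# t statistics
# ---------------------------------------------------------------------------

def pooled_t(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t per column; 0 where both groups are
    constant and equal."""
    nA, nB = A.shape[0], B.shape[0]
    if nA < 2 or nB < 2:
        raise UsageError("need at least 2 observations per group")
    mA, mB = A.mean(axis=0), B.mean(axis=0)
    ssA = ((A - mA) ** 2).sum(axis=0)
    ssB = ((B - mB) ** 2).sum(axis=0)
    pooled = (ssA + ssB) / (nA + nB - 2)
    se = np.sqrt(pooled * (1.0 / nA + 1.0 / nB))
    diff = mA - mB
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    zero_se = se == 0
    if np.any(zero_se):
        t = np.where(zero_se & (diff == 0), 0.0, t)
        t = np.where(zero_se & (diff > 0), np.inf, t)
        t = np.where(zero_se & (diff < 0), -np.inf, t)
    return t


def ttest_map(
    group_a: Sequence[ScalarVolume] | np.ndarray,
    group_b: Sequence[ScalarVolume] | np.ndarray,
    mask: Optional[np.ndarray] = None,
    grid: Optional[VoxelGrid] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled two-sample t map and its sign map (sign of mean_a - mean_b)."""
    if isinstance(group_a, np.ndarray):
        A, B = np.asarray(group_a, float), np.asarray(group_b, float)
    else:
        grid = group_a[0].grid
        mask = np.ones(grid.shape, bool) if mask is None else mask
        A = np.array([v.values[mask] for v in group_a])
        B = np.array([v.values[mask] for v in group_b])
    t = pooled_t(A, B)
    return t, np.sign(A.mean(axis=0) - B.mean(axis=0))


# ---------------------------------------------------------------------------
# permutation machinery
# ---------------------------------------------------------------------------

def _distinct_two_level(labels: np.ndarray) -> int:
    """Number of distinct assignments of a two-level label multiset."""
    values, counts = np.unique(labels, return_counts=True)
    return comb(int(counts.sum()), int(counts[0]))


def _enumerate_two_level(labels: np.ndarray):
    """Yield every distinct assignment of the two-level label vector."""
    values = np.unique(labels)
    n = len(labels)
    k = int(np.sum(labels == values[0]))
    for pos in combinations(range(n), k):
        out = np.full(n, values[1], dtype=labels.dtype)
        out[list(pos)] = values[0]
        yield out


def _p_from_counts(greater_equal: int, n_perm: int) -> float:
    return (1 + greater_equal) / (1 + n_perm)


def _perm_pvals(
    observed: np.ndarray,
    perm_stat_iter,
    n_perm: int,
) -> np.ndarray:
    """(1 + #{perm >= obs}) / (1 + n_perm), streaming over permutations."""
    count = np.zeros_like(observed, dtype=np.int64)
    total = 0
    for stat in perm_stat_iter:
        count += stat >= observed - 1e-12
        total += 1
    if total != n_perm:
        raise RuntimeError(f"expected {n_perm} permutations, got {total}")
    return (1 + count) / (1 + n_perm)


def _f_effect_iter(Y, side, treat, effect: Effect, perms, tss=None):
    """Yield permuted F statistics for one ANOVA effect.

    ``perms`` yields index arrays to reorder the label vector(s) under test.
    """
    for idx in perms:
        if effect == "side":
            fs = _f_from_labels(Y, side[idx], treat, tss)
        elif effect == "treatment":
            fs = _f_from_labels(Y, side, treat[idx], tss)
        else:  # interaction: synchronised full-label permutation
            fs = _f_from_labels(Y, side[idx], treat[idx], tss)
        yield np.nan_to_num(fs[effect], posinf=np.inf)


def _random_perm_indices(n: int, n_perm: int, rng: np.random.Generator):
    for _ in range(n_perm):
        yield rng.permutation(n)


def permutation_fmap(
    obs: ObservationSet,
    effect: Effect,
    n_perm: int = 18000,
    seed: int = 0,
) -> StatMap:
    """Permutation p-map for one 2x2 ANOVA effect."""
    if n_perm < 1:
        raise UsageError("n_perm must be >= 1")
    for cell, count in obs.n_per_cell().items():
        if count < 1:
            raise UsageError(f"empty design cell {cell}")
    side_pm = _codes(obs.side, "ipsi")
    treat_pm = _codes(obs.treatment, "lesion")
    Y = obs.data
    tss = np.einsum("ij,ij->j", Y, Y)
    observed = np.nan_to_num(
        _f_from_labels(Y, side_pm, treat_pm, tss)[effect], posinf=np.inf
    )

    labels = side_pm if effect == "side" else treat_pm
    if effect in ("side", "treatment"):
        n_distinct = _distinct_two_level(labels)
    else:
        n_distinct = None  # joint relabellings; practically always sampled

    rng = np.random.default_rng(seed)
    if effect in ("side", "treatment") and n_distinct - 1 <= n_perm:
        # exact: enumerate all distinct assignments except the observed one
        def perm_iter():
            for assign in _enumerate_two_level(labels):
                if np.array_equal(assign, labels):
                    continue
                if effect == "side":
                    fs = _f_from_labels(Y, assign, treat_pm, tss)
                else:
                    fs = _f_from_labels(Y, side_pm, assign, tss)
                yield np.nan_to_num(fs[effect], posinf=np.inf)

        p = _perm_pvals(observed, perm_iter(), n_distinct - 1)
        estimator = "exact"
        n_used = n_distinct - 1
    else:
        p = _perm_pvals(
            observed,
            _f_effect_iter(
                Y, side_pm, treat_pm, effect,
                _random_perm_indices(len(side_pm), n_perm, rng), tss,
            ),
            n_perm,
        )
        estimator = "monte-carlo"
        n_used = n_perm

    return StatMap(
        stat=observed,
        p=p,
        mask=obs.mask,
        grid=obs.grid,
        metadata=dict(
            contrast=f"F_{effect}",
            n_per_cell={f"{k[0]}/{k[1]}": v for k, v in obs.n_per_cell().items()},
            n_perm=n_used,
            seed=seed,
            estimator=estimator,
        ),
    )


def permutation_tmap(
    A: np.ndarray,
    B: np.ndarray,
    n_perm: int = 18000,
    seed: int = 0,
    contrast: str = "t_contrast",
    mask: Optional[np.ndarray] = None,
    grid: Optional[VoxelGrid] = None,
) -> StatMap:
    """Two-sided permutation p-map for a two-sample pooled-t contrast.

    The permutation statistic is |t|; group labels are shuffled across the
    pooled observations.  Exact enumeration is used when feasible.
    """
    if n_perm < 1:
        raise UsageError("n_perm must be >= 1")
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    nA, nB = A.shape[0], B.shape[0]
    Y = np.vstack([A, B])
    labels = np.array(["a"] * nA + ["b"] * nB)
    t_obs = pooled_t(A, B)
    observed = np.abs(np.nan_to_num(t_obs, posinf=np.inf, neginf=-np.inf))

    n_distinct = comb(nA + nB, nA)
    rng = np.random.default_rng(seed)

    def stat_for(assign: np.ndarray) -> np.ndarray:
        t = pooled_t(Y[assign == "a"], Y[assign == "b"])
        return np.abs(np.nan_to_num(t, posinf=np.inf, neginf=-np.inf))

    if n_distinct - 1 <= n_perm:
        def perm_iter():
            for assign in _enumerate_two_level(labels):
                if np.array_equal(assign, labels):
                    continue
                yield stat_for(assign)

        p = _perm_pvals(observed, perm_iter(), n_distinct - 1)
        estimator = "exact"
        n_used = n_distinct - 1
    else:
        def perm_iter():
            for _ in range(n_perm):
                yield stat_for(labels[rng.permutation(nA + nB)])

        p = _perm_pvals(observed, perm_iter(), n_perm)
        estimator = "monte-carlo"
        n_used = n_perm

    sign = np.sign(A.mean(axis=0) - B.mean(axis=0))
    return StatMap(
        stat=np.abs(t_obs),
        p=p,
        mask=mask if mask is not None else np.ones((1, 1, 1), bool),
        grid=grid if grid is not None else VoxelGrid((1, 1, 1), (1.0, 1.0, 1.0)),
        sign=sign,
        metadata=dict(
            contrast=contrast,
            n=[int(nA), int(nB)],
            n_perm=n_used,
            seed=seed,
            estimator=estimator,
        ),
    )


def permutation_pmap(
    obs: ObservationSet,
    statistic: str,
    n_perm: int = 18000,
    seed: int = 0,
    contrast_groups: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> StatMap:
    """Dispatch to the F- or t-statistic permutation test.

    ``statistic`` is one of F_side, F_treatment, F_interaction, t_contrast;
    for t_contrast pass the two group observation matrices."""
    if statistic.startswith("F_"):
        return permutation_fmap(obs, statistic[2:], n_perm=n_perm, seed=seed)
    if statistic == "t_contrast":
        if contrast_groups is None:
            raise UsageError("t_contrast requires contrast_groups=(A, B)")
        A, B = contrast_groups
        return permutation_tmap(A, B, n_perm=n_perm, seed=seed, mask=obs.mask, grid=obs.grid)
    raise UsageError(f"unknown statistic {statistic!r}")


# ---------------------------------------------------------------------------
# post hoc contrasts
# ---------------------------------------------------------------------------

def _subgroup(obs: ObservationSet, side=None, treatment=None) -> np.ndarray:
    sel = np.ones(len(obs.side), dtype=bool)
    if side is not None:
        sel &= obs.side == side
    if treatment is not None:
        sel &= obs.treatment == treatment
    return obs.data[sel]


def posthoc_contrasts(
    obs: ObservationSet,
    anova_pmaps: dict[str, StatMap],
    alpha: float = 0.05,
    n_perm: int = 18000,
    seed: int = 0,
    gating: Literal["union", "per-effect"] = "union",
) -> dict[str, StatMap]:
    """The four pair-wise contrasts, evaluated only on voxels where any
    ANOVA effect reached uncorrected p < alpha (union gating by default)."""
    for m in anova_pmaps.values():
        if m.grid != obs.grid or m.mask.shape != obs.mask.shape:
            raise GeometryError("ANOVA p-maps must share the observation grid/mask")

    sig = {name: m.p < alpha for name, m in anova_pmaps.items()}
    union_gate = np.logical_or.reduce(list(sig.values()))

    def gate_for(contrast: str) -> np.ndarray:
        if gating == "union":
            return union_gate
        # per-effect: a side contrast is gated by the side and interaction
        # effects, a treatment contrast by treatment and interaction
        main = "side" if "ipsi_vs_contra" in contrast else "treatment"
        parts = [sig[k] for k in (f"{main}", "interaction") if k in sig]
        return np.logical_or.reduce(parts) if parts else union_gate

    specs = {
        "lesion_ipsi_vs_contra": (
            _subgroup(obs, side="ipsi", treatment="lesion"),
            _subgroup(obs, side="contra", treatment="lesion"),
        ),
        "vehicle_ipsi_vs_contra": (
            _subgroup(obs, side="ipsi", treatment="vehicle"),
            _subgroup(obs, side="contra", treatment="vehicle"),
        ),
        "lesion_vs_vehicle_ipsi": (
            _subgroup(obs, side="ipsi", treatment="lesion"),
            _subgroup(obs, side="ipsi", treatment="vehicle"),
        ),
        "lesion_vs_vehicle_contra": (
            _subgroup(obs, side="contra", treatment="lesion"),
            _subgroup(obs, side="contra", treatment="vehicle"),
        ),
    }

    out = {}
    rng = np.random.default_rng(seed)
    for name, (A, B) in specs.items():
        sub_seed = int(rng.integers(2**31 - 1))
        g = gate_for(name)
        sm = permutation_tmap(
            A[:, g], B[:, g], n_perm=n_perm, seed=sub_seed, contrast=name,
        )
        # re-embed onto the full mask: p=1 (inactive) outside the gate
        p_full = np.ones(obs.data.shape[1])
        stat_full = np.zeros(obs.data.shape[1])
        sign_full = np.zeros(obs.data.shape[1])
        p_full[g] = sm.p
        stat_full[g] = sm.stat
        sign_full[g] = sm.sign
        out[name] = StatMap(
            stat=stat_full,
            p=p_full,
            mask=obs.mask,
            grid=obs.grid,
            sign=sign_full,
            metadata={**sm.metadata, "gate_voxels": int(g.sum()), "alpha": alpha,
                      "gating": gating},
        )
        out[name].gate = np.array(g)  # type: ignore[attr-defined]
    return out
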