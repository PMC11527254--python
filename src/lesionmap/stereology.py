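"""Optical-fractionator stereology and the 2D mean-fluorescence ratio.

The estimator is the standard optical fractionator
``N = sum(Q) * (1/ssf) * (1/asf) * (1/tsf)`` where ssf/asf/tsf are the
section, area and thickness sampling fractions.  The count-weighted mean
section thickness is ``t_bar = sum(t_i * Q_i) / sum(Q_i)``; by default the
disector height equals the measured mean thickness (tsf = 1) since guard
zones are a per-study choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .volume_core import UsageError


class UndefinedThicknessError(ValueError):
    pass


class UndefinedRatioError(ValueError):
    pass


@dataclass(frozen=True)
class SectionTrace:
    """One traced section: polygon outline (um) plus counting sites."""

    section_index: int
    vertices: tuple  # ordered (x, y) pairs, um
    thicknesses: tuple = ()  # t_i per counting site, um
    counts: tuple = ()  # Q_i per counting site

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise UsageError("a section trace needs at least 3 vertices")
        if any(t <= 0 for t in self.thicknesses):
            raise UsageError("section thicknesses must be positive")
        if any(q < 0 for q in self.counts):
            raise UsageError("particle counts must be non-negative")
        if len(self.thicknesses) != len(self.counts):
            raise UsageError("one thickness per counting site is required")


@dataclass(frozen=True)
class FractionatorParams:
    """Sampling fractions of the fractionator design, each in (0, 1]."""

    ssf: float = 1.0 / 6.0  # section sampling fraction
    asf: float = 0.20  # area sampling fraction
    tsf: float = 1.0  # thickness sampling fraction (disector height / t_bar)

    def __post_init__(self) -> None:
        for name, v in (("ssf", self.ssf), ("asf", self.asf), ("tsf", self.tsf)):
            if not (0.0 < v <= 1.0):
                raise UsageError(f"{name} must lie in (0, 1], got {v}")


def polygon_area(vertices: Sequence[Sequence[float]]) -> float:
    """Shoelace area of a simple polygon, orientation-independent (um^2)."""
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[0] < 3 or v.shape[1] != 2:
        raise UsageError("polygon_area needs >= 3 (x, y) vertices")
    x, y = v[:, 0], v[:, 1]
    x2, y2 = np.roll(x, -1), np.roll(y, -1)
    return float(abs(0.5 * np.sum(x * y2 - x2 * y)))


def mean_section_thickness(sites: Sequence[tuple[float, float]]) -> float:
    """Count-weighted mean thickness: sum(t_i Q_i) / sum(Q_i)."""
    arr = np.asarray(sites, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise UsageError("sites must be (thickness, count) pairs")
    t, q = arr[:, 0], arr[:, 1]
    if q.sum() <= 0:
        raise UndefinedThicknessError("total particle count is zero")
    return float(np.sum(t * q) / np.sum(q))


def fractionator_estimate(sum_q: int, params: FractionatorParams) -> float:
    """Total-number estimate: sum(Q) / (ssf * asf * tsf)."""
    if sum_q < 0:
        raise UsageError("sum_q must be >= 0")
    return float(sum_q) / (params.ssf * params.asf * params.tsf)


def section_sampling(
    n_sections: int,
    period: int = 6,
    random_start: bool = False,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Systematic sampling: indices {s, s+period, ...}; ``s`` is uniform in
    [0, period) when random_start, else 0."""
    if period < 1:
        raise UsageError("period must be >= 1")
    start = 0
    if random_start:
        start = int(np.random.default_rng(seed).integers(period))
    return np.arange(start, n_sections, period)


def mfi_ratio(mean_ipsi: float, mean_contra: float) -> float:
    """Ipsi/contra mean-fluorescence ratio as a percentage."""
    if mean_contra <= 0:
        raise UndefinedRatioError("contralateral mean must be positive")
    return 100.0 * mean_ipsi / mean_contra


# ---------------------------------------------------------------------------
# per-animal summary and CSV interfaces
# ---------------------------------------------------------------------------

def animal_estimate(
    traces: Sequence[SectionTrace], params: Optional[FractionatorParams] = None
) -> dict:
    """Aggregate traces of one animal into the fractionator summary."""
    sites = [(t, q) for tr in traces for t, q in zip(tr.thicknesses, tr.counts)]
    sum_q = int(sum(q for _, q in sites))
    t_bar = mean_section_thickness(sites) if sum_q > 0 else float("nan")
    params = params or FractionatorParams()
    return dict(
        n_sections=len(traces),
        total_area_um2=float(sum(polygon_area(tr.vertices) for tr in traces)),
        sum_q=sum_q,
        mean_thickness_um=t_bar,
        ssf=params.ssf,
        asf=params.asf,
        tsf=params.tsf,
        n_estimate=fractionator_estimate(sum_q, params),
    )


def read_traces_csv(vertices_csv, sites_csv) -> list[SectionTrace]:
    """Load traces from a vertices CSV (section_index, vertex_order, x_um,
    y_um) and a sites CSV (section_index, site_index, thickness_um, count)."""
    vdf = pd.read_csv(vertices_csv).sort_values(["section_index", "vertex_order"])
    sdf = pd.read_csv(sites_csv).sort_values(["section_index", "site_index"])
    traces = []
    for sec, grp in vdf.groupby("section_index"):
        sgrp = sdf[sdf["section_index"] == sec]
        traces.append(
            SectionTrace(
                section_index=int(sec),
                vertices=tuple(zip(grp["x_um"], grp["y_um"])),
                thicknesses=tuple(sgrp["thickness_um"]),
                counts=tuple(sgrp["count"]),
            )
        )
    return traces
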