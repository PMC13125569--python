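"""Deflection → traction force conversion and time-course summaries.

Tissue tension F is obtained from post deflection δ by Hooke's law,
F = k·δ, with k the calibrated spring constant. Because the imaging readout
is the inter-bead gap closure — the sum of both posts' deflections in a
symmetric two-post tether — the default convention halves the gap closure:
F = k·Δd/2. Forces can be normalised per seeded cell, split into active
(myosin-dependent) and residual (matrix-stored) tension around a drug
stimulation, and aggregated over constructs per experimental group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .tracking import DeflectionSeries

__all__ = [
    "ForceTimecourse",
    "CellNormalization",
    "TensionSplit",
    "force_from_deflection",
    "per_cell_force",
    "split_active_residual",
    "summarize_groups",
]


@dataclass(frozen=True)
class ForceTimecourse:
    """Tissue tension per timepoint for one construct."""

    times: np.ndarray  # hours
    force_uN: np.ndarray
    k_used: float  # µN/µm
    mode: str = "symmetric_pair"
    construct_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "force_uN", np.asarray(self.force_uN, dtype=float))
        if self.times.shape != self.force_uN.shape:
            raise InputError("times and force_uN must have equal length")
        if self.mode not in ("symmetric_pair", "per_post"):
            raise InputError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class CellNormalization:
    """Initial seeding: 90 µl of gel at 1×10⁶ cells/ml → 90 000 cells."""

    gel_volume_ul: float = 90.0
    seeding_density_per_ml: float = 1e6

    @property
    def n_cells(self) -> float:
        n = self.gel_volume_ul * 1e-3 * self.seeding_density_per_ml
        if n <= 0:
            raise InputError("n_cells must be > 0")
        return n


@dataclass(frozen=True)
class TensionSplit:
    """Decomposition of pre-stimulation tension into releasable and stored parts."""

    active_uN: float
    residual_uN: float
    stim_time_h: float
    plateau_window_h: tuple


def force_from_deflection(
    series: DeflectionSeries,
    k: float,
    mode: str = "symmetric_pair",
    construct_id: str = "",
    group: str = "",
) -> ForceTimecourse:
    """Hooke's-law conversion of a deflection series to a force time course.

    ``symmetric_pair`` (default): F(t) = k·Δd(t)/2, where Δd is the total gap
    closure shared equally by the two posts. ``per_post``: F(t) = k·δ(t) with
    δ the deflection of a single post.
    """
    if k <= 0:
        raise InputError(f"spring constant must be > 0, got {k}")
    defl = series.total_deflection_um
    if mode == "symmetric_pair":
        force = k * defl / 2.0
    elif mode == "per_post":
        force = k * defl
    else:
        raise InputError(f"unknown mode {mode!r}")
    return ForceTimecourse(
        times=series.times,
        force_uN=force,
        k_used=float(k),
        mode=mode,
        construct_id=construct_id,
        group=group,
    )


def per_cell_force(tc: ForceTimecourse, norm: CellNormalization) -> np.ndarray:
    """Force per initially seeded cell, in nN/cell (µN × 1000 / n_cells)."""
    return tc.force_uN * 1000.0 / norm.n_cells


def split_active_residual(
    tc: ForceTimecourse,
    stim_time_h: float,
    plateau_window_h: tuple,
) -> TensionSplit:
    """Split tension around a relaxing stimulation (e.g. blebbistatin).

    Residual tension is the mean force over the post-stimulation plateau
    window; active tension is the last pre-stimulation force minus the
    residual.
    """
    t = tc.times
    lo, hi = plateau_window_h
    if not (t.min() <= stim_time_h <= t.max()):
        raise InputError(
            f"stim_time_h {stim_time_h} outside record [{t.min()}, {t.max()}]"
        )
    if lo < stim_time_h or hi > t.max() or lo >= hi:
        raise InputError(
            f"plateau window {plateau_window_h} must lie within "
            f"[{stim_time_h}, {t.max()}]"
        )
    pre = t <= stim_time_h
    if not pre.any():
        raise InputError("no samples before stimulation")
    in_win = (t >= lo) & (t <= hi)
    if not in_win.any():
        raise InputError("no samples inside plateau window")
    residual = float(np.mean(tc.force_uN[in_win]))
    pre_level = float(tc.force_uN[pre][-1])
    return TensionSplit(
        active_uN=pre_level - residual,
        residual_uN=residual,
        stim_time_h=float(stim_time_h),
        plateau_window_h=(float(lo), float(hi)),
    )


def _align_times(tcs: Sequence[ForceTimecourse],
                 match_tol_h: float) -> np.ndarray:
    """Common time grid: union of times merged within the matching tolerance."""
    all_t = np.sort(np.unique(np.concatenate([tc.times for tc in tcs])))
    grid = [all_t[0]]
    for t in all_t[1:]:
        if t - grid[-1] > match_tol_h:
            grid.append(t)
    return np.array(grid)


def summarize_groups(
    tcs: Sequence[ForceTimecourse],
    reference_group: Optional[str] = None,
    match_tol_h: float = 0.25,
) -> tuple[pd.DataFrame, Optional[pd.DataFrame]]:
    """Per-time, per-group mean ± SEM and fold changes versus a reference.

    Constructs are aligned on a shared grid by nearest-sample matching within
    ``match_tol_h`` (default ±15 min), falling back to linear interpolation
    inside each record's span. Returns (summary, fold) DataFrames; ``fold``
    is None when no reference group is requested. Fold change is
    mean/mean(reference) at each time, percent change is 100×(fold − 1).
    """
    if not tcs:
        raise InputError("no time courses to summarize")
    groups = sorted({tc.group for tc in tcs})
    if reference_group is not None and reference_group not in groups:
        raise InputError(f"reference group {reference_group!r} not present")
    grid = _align_times(tcs, match_tol_h)

    def sample(tc: ForceTimecourse, t: float) -> float:
        i = int(np.argmin(np.abs(tc.times - t)))
        if abs(tc.times[i] - t) <= match_tol_h:
            return float(tc.force_uN[i])
        if tc.times.min() <= t <= tc.times.max():
            return float(np.interp(t, tc.times, tc.force_uN))
        return np.nan

    rows = []
    for t in grid:
        for g in groups:
            vals = np.array([sample(tc, t) for tc in tcs if tc.group == g])
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                continue
            sem = float(np.std(vals, ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
            rows.append({"time_h": float(t), "group": g,
                         "mean_uN": float(np.mean(vals)), "sem_uN": sem,
                         "n": int(vals.size)})
    summary = pd.DataFrame(rows)
    fold = None
    if reference_group is not None:
        ref = summary[summary.group == reference_group].set_index("time_h")["mean_uN"]
        frows = []
        for _, r in summary.iterrows():
            if r.time_h in ref.index and ref[r.time_h] != 0:
                f = r.mean_uN / ref[r.time_h]
                frows.append({"time_h": r.time_h, "group": r.group,
                              "fold": f, "percent_change": 100.0 * (f - 1.0)})
        fold = pd.DataFrame(frows)
    return summary, fold
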