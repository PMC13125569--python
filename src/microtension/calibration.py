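"""Spring-constant estimation from force–displacement calibration sweeps.

A piezoresistive probe pushes the bead-capped post sideways and records force
versus imposed displacement; Hooke's law makes the spring constant the slope
of that line, k = ΔF/Δδ. The slope is estimated by ordinary least squares
with a free intercept (probe contact offset), and per-post estimates are
aggregated per boundary condition (PDMS mixing ratio).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import InputError

__all__ = [
    "CalibrationCurve",
    "SpringConstantEstimate",
    "fit_spring_constant",
    "summarize_condition",
    "DEFAULT_FORCE_CEILING",
]

#: Maximum probe force per boundary condition (µN): the sweep stops at 400 µN
#: on compliant posts and 4000 µN on rigid posts.
DEFAULT_FORCE_CEILING = {"compliant": 400.0, "rigid": 4000.0}


@dataclass(frozen=True)
class CalibrationCurve:
    """One probe sweep: displacement (µm) vs force (µN) for a single post."""

    displacement: np.ndarray
    force: np.ndarray
    post_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "displacement",
                           np.asarray(self.displacement, dtype=float))
        object.__setattr__(self, "force", np.asarray(self.force, dtype=float))
        if self.displacement.shape != self.force.shape:
            raise InputError("displacement and force must have equal length")
        if self.displacement.size < 3:
            raise InputError(
                f"calibration needs ≥3 samples, got {self.displacement.size}"
            )
        if not np.all(np.diff(self.displacement) > 0):
            raise InputError("displacement must be strictly increasing")
        if not np.all(np.isfinite(self.force)):
            raise InputError("forces must be finite")

    def truncated(self, force_ceiling: float) -> "CalibrationCurve":
        """Drop samples beyond the sensor force ceiling (µN)."""
        keep = self.force <= force_ceiling
        return replace(self, displacement=self.displacement[keep],
                       force=self.force[keep])


@dataclass(frozen=True)
class SpringConstantEstimate:
    k: float
    intercept: float
    stderr_k: float
    r_squared: float
    n_points: int
    post_id: str = ""
    condition: str = ""
    valid: bool = True

    def __post_init__(self) -> None:
        if self.valid and self.k <= 0:
            object.__setattr__(self, "valid", False)


def fit_spring_constant(
    curve: CalibrationCurve,
    force_ceiling: Optional[float] = None,
) -> SpringConstantEstimate:
    """OLS fit force = k·displacement + intercept; the slope is the spring constant.

    ``force_ceiling`` (µN) optionally truncates the sweep before fitting
    (defaults per condition in :data:`DEFAULT_FORCE_CEILING`). A fitted
    k ≤ 0 is returned flagged invalid rather than raised.
    """
    if force_ceiling is None and curve.condition in DEFAULT_FORCE_CEILING:
        force_ceiling = DEFAULT_FORCE_CEILING[curve.condition]
    if force_ceiling is not None:
        curve = curve.truncated(force_ceiling)
        if curve.displacement.size < 3:
            raise InputError(
                "fewer than 3 samples remain below the force ceiling "
                f"{force_ceiling} µN"
            )
    x, y = curve.displacement, curve.force
    if np.ptp(x) == 0:
        raise InputError("zero displacement variance: degenerate sweep")
    res = stats.linregress(x, y)
    return SpringConstantEstimate(
        k=float(res.slope),
        intercept=float(res.intercept),
        stderr_k=float(res.stderr),
        r_squared=float(res.rvalue**2),
        n_points=int(x.size),
        post_id=curve.post_id,
        condition=curve.condition,
    )


def summarize_condition(
    estimates: Iterable[SpringConstantEstimate],
) -> dict:
    """Mean/SD/SEM of k over the valid estimates of one boundary condition.

    Invalid estimates (non-positive slope) are excluded and counted. A single
    valid estimate reports sd = sem = 0.
    """
    estimates = list(estimates)
    if not estimates:
        raise InputError("no estimates to summarize")
    valid = [e for e in estimates if e.valid]
    if not valid:
        raise InputError("no valid estimates to summarize")
    ks = np.array([e.k for e in valid])
    n = ks.size
    sd = float(np.std(ks, ddof=1)) if n > 1 else 0.0
    return {
        "mean_k": float(np.mean(ks)),
        "sd_k": sd,
        "sem_k": sd / np.sqrt(n) if n > 1 else 0.0,
        "n": int(n),
        "n_invalid": len(estimates) - n,
    }
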