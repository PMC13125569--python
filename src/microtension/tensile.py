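"""Fascicle ramp-to-failure tensile analysis.

Tail-tendon fascicles are tested grip-to-grip on a uniaxial device:
preload to 0.015 N defines the zero-strain reference, nominal stress uses
the initial cross-sectional area of an assumed perfect cylinder, the tangent
elastic modulus is the least-squares slope of stress–strain inside the
0.5–1% linear window, and failure metrics come from the global force
maximum of the ramp. Specimens thinner than 90 µm fail QC and are discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import InputError

__all__ = [
    "RampTest",
    "MechanicalSummary",
    "qc_filter",
    "preload_offset",
    "stress_strain",
    "tangent_modulus",
    "failure_metrics",
    "final_ramp_segment",
    "analyze_ramp",
    "DEFAULT_PRELOAD_N",
    "DEFAULT_TANGENT_WINDOW",
    "DEFAULT_MIN_DIAMETER_UM",
]

DEFAULT_PRELOAD_N = 0.015
DEFAULT_TANGENT_WINDOW = (0.005, 0.010)
DEFAULT_MIN_DIAMETER_UM = 90.0


@dataclass(frozen=True)
class RampTest:
    """Load–displacement record of one fascicle plus its geometry.

    ``displacement_mm`` must be non-decreasing on the failure ramp (use
    :func:`final_ramp_segment` to strip preconditioning cycles first).
    """

    displacement_mm: np.ndarray
    force_N: np.ndarray
    diameter_um: float
    gauge_length_mm: float
    rate_mm_s: float = 1.0
    specimen_id: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.displacement_mm, dtype=float)
        f = np.asarray(self.force_N, dtype=float)
        if d.shape != f.shape or d.size < 3:
            raise InputError("displacement and force must be equal-length, ≥3 samples")
        if np.any(np.diff(d) < 0):
            raise InputError("displacement must be non-decreasing on the ramp")
        if self.diameter_um <= 0 or self.gauge_length_mm <= 0:
            raise InputError("diameter and gauge length must be > 0")
        object.__setattr__(self, "displacement_mm", d)
        object.__setattr__(self, "force_N", f)

    @property
    def csa_mm2(self) -> float:
        """Cross-sectional area of the assumed cylinder, π(d/2)² in mm²."""
        r_mm = self.diameter_um / 2000.0
        return math.pi * r_mm**2


@dataclass(frozen=True)
class MechanicalSummary:
    csa_mm2: float
    E_MPa: float
    failure_force_N: float
    failure_stress_MPa: float
    failure_strain: float
    stiffness_N_mm: float
    qc_pass: bool
    qc_reason: str = ""
    specimen_id: str = ""


def qc_filter(test: RampTest,
              min_diameter_um: float = DEFAULT_MIN_DIAMETER_UM) -> tuple[bool, str]:
    """Diameter gate: specimens with d < 90 µm are discarded (boundary passes)."""
    if test.diameter_um < min_diameter_um:
        return False, (f"diameter {test.diameter_um} µm < "
                       f"{min_diameter_um} µm minimum")
    return True, "ok"


def preload_offset(test: RampTest,
                   preload_N: float = DEFAULT_PRELOAD_N) -> float:
    """Displacement (mm) at the first upward preload crossing: the strain origin.

    The crossing is located by linear interpolation between the bracketing
    samples. If the record starts above the preload the first sample is used
    (degenerate but tolerated).
    """
    f = test.force_N
    d = test.displacement_mm
    if f[0] >= preload_N:
        import warnings

        warnings.warn("record starts above preload; using first sample as origin",
                      stacklevel=2)
        return float(d[0])
    above = np.nonzero(f >= preload_N)[0]
    if above.size == 0:
        raise InputError(f"force never reaches preload {preload_N} N "
                         f"(max {f.max():.4g} N)")
    i = int(above[0])
    if f[i] == f[i - 1]:
        return float(d[i])
    frac = (preload_N - f[i - 1]) / (f[i] - f[i - 1])
    return float(d[i - 1] + frac * (d[i] - d[i - 1]))


def stress_strain(test: RampTest, offset_mm: float) -> tuple[np.ndarray, np.ndarray]:
    """Nominal strain and stress: ε = (x − x₀)/L_gauge, σ = F/CSA (MPa)."""
    strain = (test.displacement_mm - offset_mm) / test.gauge_length_mm
    stress = test.force_N / test.csa_mm2  # N/mm² = MPa
    return strain, stress


def _window_slope(x: np.ndarray, y: np.ndarray,
                  window: tuple, what: str) -> float:
    lo, hi = window
    inside = (x >= lo) & (x <= hi)
    n = int(inside.sum())
    if n < 3:
        raise InputError(
            f"only {n} samples inside the {what} window [{lo}, {hi}]; need ≥3"
        )
    A = np.vstack([x[inside], np.ones(n)]).T
    slope, _ = np.linalg.lstsq(A, y[inside], rcond=None)[0]
    return float(slope)


def tangent_modulus(strain: np.ndarray, stress: np.ndarray,
                    window: tuple = DEFAULT_TANGENT_WINDOW) -> float:
    """Least-squares slope of stress vs strain inside the linear window (MPa)."""
    strain = np.asarray(strain, dtype=float)
    stress = np.asarray(stress, dtype=float)
    return _window_slope(strain, stress, window, "tangent-modulus strain")


def failure_metrics(test: RampTest, offset_mm: float,
                    window: tuple = DEFAULT_TANGENT_WINDOW) -> dict:
    """Failure force/stress/strain at the global force maximum, plus stiffness.

    Stiffness is the force–displacement slope over the same strain window
    mapped to displacement. A record whose force maximum is the final sample
    is flagged "no failure detected" (the ramp ended before rupture).
    """
    strain, _ = stress_strain(test, offset_mm)
    i_max = int(np.argmax(test.force_N))
    no_failure = i_max == len(test.force_N) - 1
    disp_window = (offset_mm + window[0] * test.gauge_length_mm,
                   offset_mm + window[1] * test.gauge_length_mm)
    stiffness = _window_slope(test.displacement_mm, test.force_N,
                              disp_window, "stiffness displacement")
    return {
        "failure_force_N": float(test.force_N[i_max]),
        "failure_stress_MPa": float(test.force_N[i_max] / test.csa_mm2),
        "failure_strain": float(strain[i_max]),
        "stiffness_N_mm": stiffness,
        "no_failure_detected": bool(no_failure),
    }


def final_ramp_segment(displacement_mm, force_N) -> tuple[np.ndarray, np.ndarray]:
    """Strip preconditioning cycles: keep the final monotone-rising segment.

    Displacement reversals tag cycle boundaries; everything from the last
    reversal onward is the failure ramp.
    """
    d = np.asarray(displacement_mm, dtype=float)
    f = np.asarray(force_N, dtype=float)
    drops = np.nonzero(np.diff(d) < 0)[0]
    start = int(drops[-1]) + 1 if drops.size else 0
    return d[start:], f[start:]


def analyze_ramp(test: RampTest,
                 preload_N: float = DEFAULT_PRELOAD_N,
                 window: tuple = DEFAULT_TANGENT_WINDOW,
                 min_diameter_um: float = DEFAULT_MIN_DIAMETER_UM) -> MechanicalSummary:
    """Full per-specimen pipeline: QC → preload origin → modulus → failure."""
    ok, reason = qc_filter(test, min_diameter_um)
    if not ok:
        return MechanicalSummary(
            csa_mm2=test.csa_mm2, E_MPa=float("nan"),
            failure_force_N=float("nan"), failure_stress_MPa=float("nan"),
            failure_strain=float("nan"), stiffness_N_mm=float("nan"),
            qc_pass=False, qc_reason=reason, specimen_id=test.specimen_id,
        )
    offset = preload_offset(test, preload_N)
    strain, stress = stress_strain(test, offset)
    E = tangent_modulus(strain, stress, window)
    fm = failure_metrics(test, offset, window)
    return MechanicalSummary(
        csa_mm2=test.csa_mm2,
        E_MPa=E,
        failure_force_N=fm["failure_force_N"],
        failure_stress_MPa=fm["failure_stress_MPa"],
        failure_strain=fm["failure_strain"],
        stiffness_N_mm=fm["stiffness_N_mm"],
        qc_pass=True,
        qc_reason="no failure detected" if fm["no_failure_detected"] else "ok",
        specimen_id=test.specimen_id,
    )
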