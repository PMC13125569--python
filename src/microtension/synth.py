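"""Seeded synthetic-data generators with machine-readable ground truth.

Every generator emulates one input modality of the platform — two-bead
brightfield frames, probe calibration sweeps, fascicle ramp-to-failure
records, DSC endotherms, oriented stripe textures, elliptical nuclei masks
and logistic force time courses — and returns the data together with a truth
table sufficient to compute every downstream metric without re-deriving it.
Identical (seed, parameters) produce bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve
from .errors import DomainError, InputError
from .forces import ForceTimecourse
from .tensile import RampTest
from .thermal import Endotherm
from .tracking import ImageFrame

__all__ = [
    "SyntheticScenario",
    "render_bead_stack",
    "logistic_gap_trajectory",
    "simulate_calibration",
    "simulate_tensile",
    "simulate_tensile_cohorts",
    "simulate_endotherm",
    "simulate_texture",
    "simulate_nuclei",
    "simulate_timecourse",
]


@dataclass(frozen=True)
class SyntheticScenario:
    """Provenance record of one generated dataset: seed, kind, parameters, truth."""

    seed: Optional[int]
    kind: str
    parameters: dict = field(default_factory=dict)
    truth: object = None


# ---------------------------------------------------------------------------
# two-bead brightfield frames


def _render_disc(canvas: np.ndarray, center_rc: tuple, radius_px: float,
                 fg: float, bg: float, supersample: int = 4) -> None:
    """Paint one anti-aliased disc by area-coverage (supersampled) rendering."""
    nr, nc = canvas.shape
    r0, c0 = center_rc
    rad = int(math.ceil(radius_px)) + 2
    rlo, rhi = max(0, int(r0) - rad), min(nr, int(r0) + rad + 1)
    clo, chi = max(0, int(c0) - rad), min(nc, int(c0) + rad + 1)
    rows = np.arange(rlo, rhi)
    cols = np.arange(clo, chi)
    s = supersample
    off = (np.arange(s) + 0.5) / s - 0.5
    rr = rows[:, None] + off[None, :]  # (nrows, s) subsample coords
    cc = cols[:, None] + off[None, :]
    dr2 = (rr - r0) ** 2  # (nrows, s)
    dc2 = (cc - c0) ** 2
    inside = (dr2[:, None, :, None] + dc2[None, :, None, :]) <= radius_px**2
    coverage = inside.mean(axis=(2, 3))
    patch = canvas[rlo:rhi, clo:chi]
    patch += coverage * (fg - bg)


def render_bead_stack(
    gap_um_trajectory: Sequence[float],
    image_shape: tuple = (320, 1024),
    um_per_px: float = 6.5,
    bead_diameter_um: float = 1400.0,
    polarity: str = "dark_beads",
    noise_sd: float = 0.0,
    times_h: Optional[Sequence[float]] = None,
    seed: Optional[int] = None,
    bit_depth: int = 8,
) -> tuple[list, pd.DataFrame]:
    """Render a time series of two-bead frames with programmed gap closure.

    The beads move symmetrically inward about the field midpoint, so the
    per-post deflection at time t is (gap₀ − gap_t)/2. Returns
    (frames, truth) where truth lists per-frame sub-pixel centers, the gap in
    px and µm, and the implied per-post deflection in µm.
    """
    gaps = np.asarray(gap_um_trajectory, dtype=float)
    if gaps.size == 0:
        raise InputError("empty gap trajectory")
    if np.any(gaps <= 0):
        raise DomainError("gaps must be positive")
    if np.any(gaps <= bead_diameter_um):
        raise DomainError("beads overlap: gap must exceed one bead diameter")
    nr, nc = image_shape
    radius_px = bead_diameter_um / 2.0 / um_per_px
    half_gaps_px = gaps / 2.0 / um_per_px
    if np.any(half_gaps_px + radius_px + 2 > nc / 2) or radius_px + 2 > nr / 2:
        raise DomainError("beads exceed the field of view; enlarge image_shape")
    if times_h is None:
        times_h = np.arange(gaps.size, dtype=float)
    vmax = 2**bit_depth - 1
    bg, fg = (0.85 * vmax, 0.15 * vmax) if polarity == "dark_beads" else (
        0.15 * vmax, 0.85 * vmax)
    mid_r, mid_c = (nr - 1) / 2.0, (nc - 1) / 2.0
    rng = np.random.default_rng(seed)

    frames, rows = [], []
    for t, gap_um, hg in zip(times_h, gaps, half_gaps_px):
        canvas = np.full((nr, nc), bg, dtype=float)
        left = (mid_r, mid_c - hg)
        right = (mid_r, mid_c + hg)
        _render_disc(canvas, left, radius_px, fg, bg)
        _render_disc(canvas, right, radius_px, fg, bg)
        if noise_sd > 0:
            canvas = canvas + rng.normal(0.0, noise_sd, canvas.shape)
        canvas = np.clip(np.round(canvas), 0, vmax)
        dtype = np.uint8 if bit_depth == 8 else np.uint16
        frames.append(ImageFrame(pixels=canvas.astype(dtype),
                                 bit_depth=bit_depth, timestamp=float(t),
                                 polarity=polarity))
        rows.append({
            "time_h": float(t),
            "left_row": left[0], "left_col": left[1],
            "right_row": right[0], "right_col": right[1],
            "gap_px": 2.0 * hg, "gap_um": float(gap_um),
            "per_post_deflection_um": float((gaps[0] - gap_um) / 2.0),
            "total_deflection_um": float(gaps[0] - gap_um),
        })
    return frames, pd.DataFrame(rows)


def logistic_gap_trajectory(
    times_h: Sequence[float],
    initial_gap_um: float = 4000.0,
    total_closure_um: float = 400.0,
    rate_per_h: float = 0.4,
    t50_h: float = 8.0,
) -> np.ndarray:
    """Gap closure following a logistic rise to a plateauing maximum."""
    t = np.asarray(times_h, dtype=float)
    closure = total_closure_um / (1.0 + np.exp(-rate_per_h * (t - t50_h)))
    return initial_gap_um - closure


# ---------------------------------------------------------------------------
# calibration sweeps


def simulate_calibration(
    k_true: float,
    displacement_um: Sequence[float],
    noise_sd_uN: float = 0.0,
    n_replicates: int = 1,
    seed: Optional[int] = None,
    condition: str = "",
) -> tuple[list, dict]:
    """Linear probe sweeps force = k_true·δ + ε, ε ~ N(0, noise_sd²)."""
    if k_true <= 0:
        raise DomainError("k_true must be > 0")
    disp = np.asarray(displacement_um, dtype=float)
    rng = np.random.default_rng(seed)
    curves = []
    for i in range(n_replicates):
        noise = rng.normal(0.0, noise_sd_uN, disp.size) if noise_sd_uN > 0 else 0.0
        curves.append(CalibrationCurve(
            displacement=disp, force=k_true * disp + noise,
            post_id=f"post_{i:03d}", condition=condition,
        ))
    return curves, {"k_true": float(k_true), "noise_sd_uN": float(noise_sd_uN)}


# ---------------------------------------------------------------------------
# fascicle tensile records


def _toe_linear_stress(strain, E_MPa, toe_strain, failure_strain,
                       toe_B=200.0, drop_factor=5.0):
    """Toe-exponential σ = A(e^{Bε} − 1) smoothly joined to slope E, then a
    linear post-failure drop. Returns stress array and the toe amplitude A."""
    eps = np.asarray(strain, dtype=float)
    if toe_strain > 0:
        A = E_MPa / (toe_B * math.exp(toe_B * toe_strain))
        sigma_toe = A * (math.exp(toe_B * toe_strain) - 1.0)
        stress = np.where(
            eps <= toe_strain,
            A * (np.exp(toe_B * np.minimum(eps, toe_strain)) - 1.0),
            sigma_toe + E_MPa * (eps - toe_strain),
        )
    else:
        A = 0.0
        stress = E_MPa * eps
    sigma_fail = float(np.interp(failure_strain, eps, stress)) if eps.size else 0.0
    if toe_strain > 0:
        sigma_fail = (A * (math.exp(toe_B * failure_strain) - 1.0)
                      if failure_strain <= toe_strain
                      else A * (math.exp(toe_B * toe_strain) - 1.0)
                      + E_MPa * (failure_strain - toe_strain))
    else:
        sigma_fail = E_MPa * failure_strain
    post = eps > failure_strain
    stress = np.where(post,
                      np.maximum(sigma_fail - drop_factor * E_MPa
                                 * (eps - failure_strain), 0.0),
                      stress)
    return stress, A


def simulate_tensile(
    E_MPa: float,
    toe_strain: float = 0.004,
    failure_strain: float = 0.12,
    diameter_um: float = 350.0,
    gauge_mm: float = 20.0,
    noise_frac: float = 0.01,
    seed: Optional[int] = None,
    max_strain: float = 0.2,
    rate_mm_s: float = 1.0,
    sample_hz: float = 200.0,
    preload_N: float = 0.015,
    toe_B: float = 200.0,
    specimen_id: str = "",
) -> tuple[RampTest, dict]:
    """One ramp-to-failure record from a toe+linear+failure stress model.

    Sampled at the displacement spacing implied by the ramp rate and sampling
    frequency; force noise is multiplicative Gaussian. The truth dict carries
    the modulus, the failure point, and the closed-form preload-crossing
    strain/displacement (inverse of the toe function).
    """
    if not 0 <= toe_strain < failure_strain <= max_strain:
        raise InputError("require 0 ≤ toe_strain < failure_strain ≤ max_strain")
    csa_mm2 = math.pi * (diameter_um / 2000.0) ** 2
    d_eps = rate_mm_s / (gauge_mm * sample_hz)
    eps = np.arange(0.0, max_strain + d_eps / 2, d_eps)
    stress, A = _toe_linear_stress(eps, E_MPa, toe_strain, failure_strain,
                                   toe_B=toe_B)
    force = stress * csa_mm2
    rng = np.random.default_rng(seed)
    if noise_frac > 0:
        force = force * (1.0 + rng.normal(0.0, noise_frac, force.size))

    sigma_pre = preload_N / csa_mm2
    if toe_strain > 0 and A > 0:
        sigma_toe = A * (math.exp(toe_B * toe_strain) - 1.0)
        if sigma_pre <= sigma_toe:
            eps_pre = math.log(1.0 + sigma_pre / A) / toe_B
        else:
            eps_pre = toe_strain + (sigma_pre - sigma_toe) / E_MPa
    else:
        eps_pre = sigma_pre / E_MPa
    truth = {
        "E_MPa": float(E_MPa),
        "csa_mm2": csa_mm2,
        "toe_strain": float(toe_strain),
        "failure_strain": float(failure_strain),
        "failure_force_N": float(np.max(stress) * csa_mm2),
        "preload_strain": eps_pre,
        "preload_displacement_mm": eps_pre * gauge_mm,
    }
    test = RampTest(
        displacement_mm=eps * gauge_mm, force_N=force,
        diameter_um=diameter_um, gauge_length_mm=gauge_mm,
        rate_mm_s=rate_mm_s, specimen_id=specimen_id,
    )
    return test, truth


def simulate_tensile_cohorts(
    E_wt_MPa: float,
    percent_difference: float,
    n_per_group: int,
    dispersion_cv: float = 0.0,
    seed: Optional[int] = None,
    **tensile_kwargs,
) -> tuple[list, list, dict]:
    """Two fascicle cohorts whose mean moduli differ by ``percent_difference`` %.

    Optional mean-preserving lognormal inter-specimen dispersion of the
    modulus (coefficient of variation ``dispersion_cv``). Returns
    (wt_tests, tg_tests, truth).
    """
    rng = np.random.default_rng(seed)
    E_tg = E_wt_MPa * (1.0 + percent_difference / 100.0)
    s_ln = math.sqrt(math.log(1.0 + dispersion_cv**2)) if dispersion_cv > 0 else 0.0

    def cohort(E_group, tag):
        tests = []
        for i in range(n_per_group):
            E_i = E_group
            if s_ln > 0:
                E_i = E_group * math.exp(rng.normal(0.0, s_ln) - s_ln**2 / 2.0)
            t, _ = simulate_tensile(E_i, seed=int(rng.integers(2**31)),
                                    specimen_id=f"{tag}_{i:03d}",
                                    **tensile_kwargs)
            tests.append(t)
        return tests

    wt = cohort(E_wt_MPa, "wt")
    tg = cohort(E_tg, "tg")
    truth = {"E_wt_MPa": E_wt_MPa, "E_tg_MPa": E_tg,
             "percent_difference": percent_difference,
             "dispersion_cv": dispersion_cv}
    return wt, tg, truth


# ---------------------------------------------------------------------------
# DSC endotherms


def simulate_endotherm(
    mu_C: float = 65.0,
    sigma_C: float = 1.5,
    amplitude: float = 1.0,
    baseline_slope: float = 0.0,
    baseline_intercept: float = 0.0,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    t_range: tuple = (20.0, 100.0),
    n_samples: int = 3201,
    endo_down: bool = False,
) -> tuple[Endotherm, dict]:
    """Gaussian endotherm on a sloped linear baseline over a temperature grid.

    Truth: T_peak = µ, FWHM = 2√(2 ln 2)·σ ≈ 2.3548σ, and the tangent-onset
    T_onset = µ − 2σ (the tangent at the inflection point µ − σ meets the
    baseline at µ − 2σ).
    """
    t = np.linspace(t_range[0], t_range[1], n_samples)
    peak = amplitude * np.exp(-((t - mu_C) ** 2) / (2.0 * sigma_C**2))
    hf = baseline_intercept + baseline_slope * t + peak
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        hf = hf + rng.normal(0.0, noise_sd, hf.size)
    if endo_down:
        hf = -hf
    truth = {
        "T_peak_C": mu_C,
        "FWHM_C": 2.0 * math.sqrt(2.0 * math.log(2.0)) * sigma_C,
        "T_onset_C": mu_C - 2.0 * sigma_C,
        "amplitude": amplitude,
    }
    return Endotherm(temperature_C=t, heat_flow=hf, endo_down=endo_down), truth


# ---------------------------------------------------------------------------
# oriented textures and nuclei masks


def simulate_texture(
    theta_deg: float,
    coherence: float = 1.0,
    shape: tuple = (256, 256),
    period_px: float = 8.0,
    n_waves: int = 32,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> tuple[np.ndarray, dict]:
    """Striped texture at orientation ``theta_deg`` with tunable coherence.

    ``coherence = 1`` gives a single clean grating; lower values superpose
    waves with angle jitter of SD (1 − coherence)·45°. Angle convention
    matches :func:`microtension.morphometrics.orientation_distribution`.
    """
    if not 0.0 <= coherence <= 1.0:
        raise InputError("coherence must be in [0, 1]")
    nr, nc = shape
    rows = np.arange(nr)[:, None]
    cols = np.arange(nc)[None, :]
    rng = np.random.default_rng(seed)
    f = 1.0 / period_px
    if coherence >= 1.0:
        th = math.radians(theta_deg)
        img = 0.5 + 0.5 * np.cos(
            2.0 * np.pi * f * (cols * math.sin(th) + rows * math.cos(th)))
    else:
        jitter_sd = (1.0 - coherence) * 45.0
        img = np.zeros((nr, nc))
        for _ in range(n_waves):
            th = math.radians(theta_deg + rng.normal(0.0, jitter_sd))
            phase = rng.uniform(0.0, 2.0 * np.pi)
            img += np.cos(2.0 * np.pi * f
                          * (cols * math.sin(th) + rows * math.cos(th)) + phase)
        img = 0.5 + 0.5 * img / n_waves
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return img, {"theta_deg": float(theta_deg % 180.0), "coherence": coherence}


def _ellipse_truth(a: float, b: float) -> float:
    """Analytic circularity of an ellipse (Ramanujan perimeter)."""
    area = math.pi * a * b
    perim = math.pi * (3.0 * (a + b) - math.sqrt((3 * a + b) * (a + 3 * b)))
    return 4.0 * math.pi * area / perim**2


def simulate_nuclei(
    n: int,
    axis_ratio_mean: float = 1.5,
    axis_ratio_sd: float = 0.0,
    minor_axis_px: float = 10.0,
    seed: Optional[int] = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Labeled mask of ``n`` non-overlapping ellipses with analytic truth.

    Ellipses are laid out on a jittered grid (no overlap by construction) with
    random orientations; the truth table holds each object's semi-axes and the
    closed-form circularity 4πA/P² using the Ramanujan perimeter.
    """
    if n < 1:
        raise InputError("need n ≥ 1 nuclei")
    rng = np.random.default_rng(seed)
    ratios = np.maximum(
        rng.normal(axis_ratio_mean, axis_ratio_sd, n) if axis_ratio_sd > 0
        else np.full(n, axis_ratio_mean), 1.0)
    a_axes = ratios * minor_axis_px
    cell = int(math.ceil(2.0 * a_axes.max() + 6))
    per_side = int(math.ceil(math.sqrt(n)))
    size = per_side * cell
    mask = np.zeros((size, size), dtype=np.int32)
    rows_grid = np.arange(size)[:, None]
    cols_grid = np.arange(size)[None, :]
    records = []
    for i in range(n):
        gr, gc = divmod(i, per_side)
        r0 = gr * cell + cell / 2.0 + rng.uniform(-1, 1)
        c0 = gc * cell + cell / 2.0 + rng.uniform(-1, 1)
        a, b = float(a_axes[i]), float(minor_axis_px)
        phi = rng.uniform(0.0, np.pi)
        dr = rows_grid - r0
        dc = cols_grid - c0
        x = dc * math.cos(phi) + dr * math.sin(phi)
        y = -dc * math.sin(phi) + dr * math.cos(phi)
        inside = (x / a) ** 2 + (y / b) ** 2 <= 1.0
        mask[inside] = i + 1
        records.append({"label": i + 1, "semi_major_px": a, "semi_minor_px": b,
                        "orientation_rad": phi,
                        "circularity": _ellipse_truth(a, b)})
    return mask, pd.DataFrame(records)


# ---------------------------------------------------------------------------
# force time courses


def simulate_timecourse(
    groups: Dict[str, dict],
    n_per_group: int,
    times_h: Sequence[float],
    noise_sd_uN: float = 0.0,
    seed: Optional[int] = None,
    k_uN_per_um: float = 1.34,
) -> tuple[list, dict]:
    """Logistic force traces F(t) = plateau/(1 + e^{−rate(t − t50)}) per group.

    ``groups`` maps a label to {plateau_uN, rate_per_h, t50_h}. Additive
    Gaussian noise per sample. Truth records each group's parameters.
    """
    t = np.asarray(times_h, dtype=float)
    rng = np.random.default_rng(seed)
    tcs = []
    for name, p in groups.items():
        plateau = p["plateau_uN"]
        rate = p.get("rate_per_h", 0.4)
        t50 = p.get("t50_h", 8.0)
        for i in range(n_per_group):
            f = plateau / (1.0 + np.exp(-rate * (t - t50)))
            if noise_sd_uN > 0:
                f = f + rng.normal(0.0, noise_sd_uN, f.size)
            tcs.append(ForceTimecourse(
                times=t, force_uN=f, k_used=k_uN_per_um,
                construct_id=f"{name}_{i:03d}", group=name,
            ))
    truth = {name: dict(p) for name, p in groups.items()}
    return tcs, truth
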