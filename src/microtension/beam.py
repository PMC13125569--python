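"""Analytical beam mechanics for cantilever posts embedded in a PDMS mat.

A steel post of circular cross-section stands in an elastic PDMS foundation;
a microtissue pulls laterally on the ceramic bead glued to its free end. The
tip stiffness (spring constant, µN/µm) is predicted from Euler–Bernoulli
bending of the free segment plus the end compliance of the embedded segment
treated as a semi-infinite beam on a Winkler foundation. This replaces a full
finite-element treatment: absolute values are approximate, but the parametric
trends (foundation stiffness, mat thickness, post diameter, post height) are
captured.

Internally all lengths are converted to metres and moduli to pascals; the
returned stiffness is in µN/µm (numerically equal to N/m) and compliances in
µm/µN (numerically m/N).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, InputError

__all__ = [
    "PostGeometry",
    "MaterialProps",
    "SpringConstantPrediction",
    "second_moment",
    "rigid_clamp_spring_constant",
    "foundation_spring_constant",
    "parametric_sweep",
    "SWEEP_AXES",
]

_MM = 1e-3  # mm → m
_GPA = 1e9  # GPa → Pa
_KPA = 1e3  # kPa → Pa


@dataclass(frozen=True)
class PostGeometry:
    """Geometry of one anchoring post, lengths in millimetres.

    ``free_length`` is the active length above the PDMS surface;
    ``embedded_length`` is the portion buried in the mat. The capping bead
    provides the gel anchoring point and sets the load application height.
    """

    diameter: float = 1.0
    total_length: float = 20.0
    free_length: float = 10.0
    embedded_length: float = 10.0
    bead_diameter: float = 1.4

    def __post_init__(self) -> None:
        for name in ("diameter", "total_length", "free_length",
                     "embedded_length", "bead_diameter"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.free_length + self.embedded_length > self.total_length + 1e-9:
            raise DomainError(
                "free_length + embedded_length exceeds total_length "
                f"({self.free_length} + {self.embedded_length} > {self.total_length})"
            )


@dataclass(frozen=True)
class MaterialProps:
    """Elastic constants of post, foundation mat and bead.

    ``E_post`` in GPa (stainless steel ≈ 193), ``E_pdms`` in kPa,
    ``E_bead`` in GPa and ``rho_bead`` in kg/m³. The bead enters static
    stiffness only through its diameter (lever arm); its modulus and density
    are stored for completeness but do not affect any static prediction.
    """

    E_post: float = 193.0
    E_pdms: float = 5.0
    nu_pdms: float = 0.499
    E_bead: float = 185.0
    rho_bead: float = 2400.0

    def __post_init__(self) -> None:
        for name in ("E_post", "E_pdms", "E_bead"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0.0 < self.nu_pdms <= 0.499:
            raise DomainError(f"nu_pdms must be in (0, 0.499], got {self.nu_pdms}")

    @property
    def winkler_modulus(self) -> float:
        """Foundation modulus k_w in N/m² per metre of embedment (i.e. N/m²).

        First-order elastic-foundation mapping k_w = E_pdms·d/(1 − ν²) is
        applied at prediction time because it needs the post diameter; this
        property returns the diameter-independent factor E_pdms/(1 − ν²) in Pa.
        """
        return self.E_pdms * _KPA / (1.0 - self.nu_pdms**2)


@dataclass(frozen=True)
class SpringConstantPrediction:
    """Predicted tip stiffness with its compliance breakdown.

    ``k`` in µN/µm; components in µm/µN sum to 1/k: free-segment bending,
    foundation end translation, and foundation end rotation carried over the
    lever arm.
    """

    k: float
    components: dict = field(default_factory=dict)

    @property
    def total_compliance(self) -> float:
        return sum(self.components.values())


def second_moment(diameter: float) -> float:
    """Second moment of area I = π·d⁴/64 of the circular section (mm⁴ for mm input)."""
    if diameter <= 0:
        raise DomainError(f"diameter must be > 0, got {diameter}")
    return math.pi * diameter**4 / 64.0


def _lever_arm_m(geom: PostGeometry, load_at_bead_center: bool) -> float:
    a = geom.free_length
    if load_at_bead_center:
        a += geom.bead_diameter / 2.0
    return a * _MM


def rigid_clamp_spring_constant(
    geom: PostGeometry,
    mat: MaterialProps,
    load_at_bead_center: bool = False,
) -> float:
    """Tip stiffness of the post clamped rigidly at the mat surface (µN/µm).

    Euler–Bernoulli cantilever limit k = 3·E·I/L³ with L the active length
    (optionally extended to the bead centre). This is the upper bound the
    foundation model approaches as the mat becomes rigid.
    """
    if geom.free_length <= 0:
        raise DomainError("free_length must be > 0")
    E = mat.E_post * _GPA
    I = second_moment(geom.diameter) * _MM**4
    L = _lever_arm_m(geom, load_at_bead_center)
    return 3.0 * E * I / L**3


def foundation_spring_constant(
    geom: PostGeometry,
    mat: MaterialProps,
    load_at_bead_center: bool = True,
) -> SpringConstantPrediction:
    """Tip stiffness of a post on a semi-infinite Winkler foundation.

    The embedded segment is a semi-infinite beam on a bed of independent
    springs of modulus k_w = E_pdms·d/(1 − ν²) per unit length. Its end
    compliance under the shear F and moment F·a transmitted by the free
    segment gives (Hetényi end-compliance matrix, characteristic length 1/λ,
    λ = (k_w/4EI)^¼):

        c_bend  = a³/(3EI)                      free-segment bending
        c_trans = (2λ + 2λ²a)/k_w               end translation (incl. moment term)
        c_rot   = (2λ²a + 4λ³a²)/k_w            end rotation carried over the lever

    with a the lever arm. k = 1/(c_bend + c_trans + c_rot). When
    embedded_length·λ < 3 the semi-infinite assumption is weak and a warning
    is emitted (the prediction is still returned).
    """
    E = mat.E_post * _GPA
    I = second_moment(geom.diameter) * _MM**4
    EI = E * I
    k_w = mat.winkler_modulus * geom.diameter * _MM  # N/m per m
    if k_w <= 0:
        raise DomainError(f"Winkler modulus must be > 0, got {k_w}")
    lam = (k_w / (4.0 * EI)) ** 0.25
    if geom.embedded_length * _MM * lam < 3.0:
        warnings.warn(
            "embedded_length·λ = "
            f"{geom.embedded_length * _MM * lam:.3g} < 3: semi-infinite "
            "foundation assumption is inaccurate for this geometry",
            stacklevel=2,
        )
    a = _lever_arm_m(geom, load_at_bead_center)
    c_bend = a**3 / (3.0 * EI)
    c_trans = (2.0 * lam + 2.0 * lam**2 * a) / k_w
    c_rot = (2.0 * lam**2 * a + 4.0 * lam**3 * a**2) / k_w
    k = 1.0 / (c_bend + c_trans + c_rot)
    return SpringConstantPrediction(
        k=k,
        components={
            "bending_compliance": c_bend,
            "foundation_translation": c_trans,
            "foundation_rotation": c_rot,
        },
    )


SWEEP_AXES = ("pdms_stiffness", "mat_thickness", "post_diameter", "post_height")


def _apply_axis(base_geom: PostGeometry, base_mat: MaterialProps,
                axis: str, value: float) -> tuple[PostGeometry, MaterialProps]:
    from dataclasses import replace

    if axis == "pdms_stiffness":
        return base_geom, replace(base_mat, E_pdms=value)
    if axis == "mat_thickness":
        free = base_geom.free_length + base_geom.embedded_length - value
        if free <= 0:
            raise DomainError(
                f"mat_thickness {value} mm leaves non-positive free length"
            )
        return replace(base_geom, embedded_length=value, free_length=free), base_mat
    if axis == "post_diameter":
        return replace(base_geom, diameter=value), base_mat
    if axis == "post_height":
        free = value - base_geom.embedded_length
        if free <= 0:
            raise DomainError(
                f"post_height {value} mm leaves non-positive free length"
            )
        return replace(base_geom, total_length=value, free_length=free), base_mat
    raise InputError(f"unknown sweep axis {axis!r}; expected one of {SWEEP_AXES}")


def parametric_sweep(
    base_geom: PostGeometry,
    base_mat: MaterialProps,
    axis: str,
    grid,
    load_at_bead_center: bool = True,
) -> pd.DataFrame:
    """Predict k along one design axis, all other parameters held at base.

    ``mat_thickness`` sweeps trade free length for embedment at fixed total
    length; ``post_height`` sweeps change total length at fixed embedment.
    Returns a DataFrame with columns axis_value, k_uN_per_um, c_bend, c_trans,
    c_rot.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise InputError("sweep grid is empty")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise InputError("sweep grid must be strictly increasing")
    rows = []
    for v in grid:
        geom, mat = _apply_axis(base_geom, base_mat, axis, float(v))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pred = foundation_spring_constant(geom, mat, load_at_bead_center)
        rows.append(
            {
                "axis_value": float(v),
                "k_uN_per_um": pred.k,
                "c_bend": pred.components["bending_compliance"],
                "c_trans": pred.components["foundation_translation"],
                "c_rot": pred.components["foundation_rotation"],
            }
        )
    return pd.DataFrame(rows)
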