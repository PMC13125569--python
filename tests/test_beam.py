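"""Beam-on-elastic-foundation spring-constant model vs independent solvers."""

import dataclasses
import math
import warnings

import numpy as np
import pytest

from microtension.beam import (MaterialProps, PostGeometry,
                               foundation_spring_constant, parametric_sweep,
                               rigid_clamp_spring_constant, second_moment)
from microtension.errors import DomainError, InputError
from oracles import (fd_tip_stiffness_cantilever, fd_tip_stiffness_foundation,
                     quadrature_second_moment)

_MM, _GPA = 1e-3, 1e9


def _EI(geom: PostGeometry, mat: MaterialProps) -> float:
    return mat.E_post * _GPA * second_moment(geom.diameter) * _MM**4


class TestSecondMoment:
    def test_closed_form_unit_diameter(self):
        assert second_moment(1.0) == pytest.approx(math.pi / 64.0)

    def test_fourth_power_scaling(self):
        assert second_moment(2.0) == pytest.approx(16.0 * second_moment(1.0))

    def test_against_quadrature(self):
        assert second_moment(1.3) == pytest.approx(
            quadrature_second_moment(1.3), rel=1e-4)

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(DomainError):
            second_moment(0.0)


class TestRigidClamp:
    def test_cube_scaling_in_free_length(self):
        m = MaterialProps()
        g1 = PostGeometry(total_length=20, free_length=5, embedded_length=10)
        g2 = PostGeometry(total_length=20, free_length=10, embedded_length=10)
        k1 = rigid_clamp_spring_constant(g1, m)
        k2 = rigid_clamp_spring_constant(g2, m)
        assert k1 == pytest.approx(8.0 * k2)

    def test_matches_discretized_beam(self):
        # steel post, d = 1 mm, E = 193 GPa, L = 10 mm
        g = PostGeometry(free_length=10, embedded_length=10)
        m = MaterialProps(E_post=193.0)
        k_fd = fd_tip_stiffness_cantilever(_EI(g, m), g.free_length * _MM)
        assert rigid_clamp_spring_constant(g, m) == pytest.approx(k_fd, rel=5e-3)

    def test_invariant_to_embedded_length(self):
        m = MaterialProps()
        g1 = PostGeometry(total_length=20, free_length=8, embedded_length=4)
        g2 = PostGeometry(total_length=20, free_length=8, embedded_length=12)
        assert rigid_clamp_spring_constant(g1, m) == rigid_clamp_spring_constant(g2, m)


class TestFoundationModel:
    def test_compliance_additivity(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pred = foundation_spring_constant(PostGeometry(), MaterialProps())
        assert 1.0 / pred.k == pytest.approx(pred.total_compliance, rel=1e-9)

    def test_monotone_in_foundation_stiffness(self):
        ks = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for e in (1.0, 5.0, 25.0, 125.0):
                m = MaterialProps(E_pdms=e)
                ks.append(foundation_spring_constant(PostGeometry(), m).k)
        assert np.all(np.diff(ks) > 0)

    def test_rigid_foundation_limit(self):
        """k converges to the rigid clamp as the foundation stiffens.

        Convergence is O(k_w^(-1/4)) through the foundation-rotation term, so
        the comparison sits deep in the stiff regime."""
        g = PostGeometry()
        m = MaterialProps(E_pdms=1e18)
        k_found = foundation_spring_constant(g, m, load_at_bead_center=True).k
        k_rigid = rigid_clamp_spring_constant(g, m, load_at_bead_center=True)
        assert abs(k_found - k_rigid) / k_rigid < 0.01

    def test_warns_when_embedment_short(self):
        with pytest.warns(UserWarning, match="semi-infinite"):
            foundation_spring_constant(PostGeometry(), MaterialProps())

    @pytest.mark.parametrize("e_pdms", [1e3, 1e4, 1e5])
    @pytest.mark.parametrize("diameter", [0.7, 1.0, 1.3])
    @pytest.mark.parametrize("free_length", [8.0, 10.0, 12.0])
    def test_matches_piecewise_ode_solution(self, e_pdms, diameter, free_length):
        """Closed-form tip stiffness vs finite-difference beam-on-foundation
        solve, inside the semi-infinite regime the model assumes."""
        g = PostGeometry(diameter=diameter, total_length=30.0,
                         free_length=free_length, embedded_length=10.0)
        m = MaterialProps(E_post=193.0, E_pdms=e_pdms)
        EI = _EI(g, m)
        k_w = m.winkler_modulus * diameter * _MM
        lam = (k_w / (4.0 * EI)) ** 0.25
        a = (free_length + g.bead_diameter / 2.0) * _MM
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            k_model = foundation_spring_constant(g, m).k
        k_fd = fd_tip_stiffness_foundation(EI, k_w, a, 12.0 / lam)
        assert k_model == pytest.approx(k_fd, rel=0.02)


class TestParametricSweep:
    @pytest.mark.parametrize("axis,grid,increasing", [
        ("pdms_stiffness", [1, 5, 25, 125], True),
        ("mat_thickness", [6, 8, 10, 12], True),   # thicker mat, shorter lever
        ("post_diameter", [0.6, 0.8, 1.0, 1.2], True),
        ("post_height", [14, 16, 18, 20], False),  # taller post, longer lever
    ])
    def test_trend_directions(self, axis, grid, increasing):
        df = parametric_sweep(PostGeometry(), MaterialProps(), axis, grid)
        diffs = np.diff(df.k_uN_per_um.to_numpy())
        assert np.all(diffs > 0) if increasing else np.all(diffs < 0)

    def test_diameter_sweep_supercubic_against_oracle(self):
        """In the foundation-rotation-dominated regime (λ·a ≫ 1) k grows at
        least as d³; soft foundations are translation-dominated and grow
        more slowly (~d^1.75)."""
        g0 = PostGeometry()
        m = MaterialProps(E_pdms=1e8)
        grid = [0.6, 0.9, 1.2, 1.5]
        df = parametric_sweep(g0, m, "post_diameter", grid)
        k = df.k_uN_per_um.to_numpy()
        d = np.asarray(grid)
        assert np.all(np.diff(k) > 0)
        exponents = np.diff(np.log(k)) / np.diff(np.log(d))
        assert np.all(exponents >= 3.0)
        # spot-check each grid point against the discretized ODE solution
        for dia, k_model in zip(grid, k):
            g = dataclasses.replace(g0, diameter=dia)
            EI = _EI(g, m)
            k_w = m.winkler_modulus * dia * _MM
            lam = (k_w / (4.0 * EI)) ** 0.25
            a = (g.free_length + g.bead_diameter / 2.0) * _MM
            k_fd = fd_tip_stiffness_foundation(EI, k_w, a, 12.0 / lam)
            assert k_model == pytest.approx(k_fd, rel=0.02)

    def test_empty_and_unsorted_grids_rejected(self):
        with pytest.raises(InputError):
            parametric_sweep(PostGeometry(), MaterialProps(), "pdms_stiffness", [])
        with pytest.raises(InputError):
            parametric_sweep(PostGeometry(), MaterialProps(), "pdms_stiffness",
                             [5, 1])

    def test_mat_thickness_consuming_free_length_rejected(self):
        with pytest.raises(DomainError):
            parametric_sweep(PostGeometry(), MaterialProps(), "mat_thickness",
                             [25.0])


class TestDomainTypes:
    def test_geometry_invariants(self):
        with pytest.raises(DomainError):
            PostGeometry(diameter=-1)
        with pytest.raises(DomainError):
            PostGeometry(free_length=15, embedded_length=10, total_length=20)

    def test_material_invariants(self):
        with pytest.raises(DomainError):
            MaterialProps(E_pdms=0)
        with pytest.raises(DomainError):
            MaterialProps(nu_pdms=0.6)
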