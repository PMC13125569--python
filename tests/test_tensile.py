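"""Fascicle tensile pipeline: QC, preload origin, modulus, failure."""

import math
import warnings

import numpy as np
import pytest

from microtension.errors import InputError
from microtension.synth import simulate_tensile, simulate_tensile_cohorts
from microtension.tensile import (RampTest, analyze_ramp, failure_metrics,
                                  final_ramp_segment, preload_offset,
                                  qc_filter, stress_strain, tangent_modulus)
from oracles import normal_equations_slope


def linear_ramp(E=600.0, d_um=350.0, gauge=20.0, n=400, max_strain=0.05):
    eps = np.linspace(0, max_strain, n)
    csa = math.pi * (d_um / 2000.0) ** 2
    return RampTest(eps * gauge, E * eps * csa, diameter_um=d_um,
                    gauge_length_mm=gauge)


class TestQC:
    @pytest.mark.parametrize("d,expected", [(89.0, False), (90.0, True),
                                            (350.0, True)])
    def test_diameter_gate(self, d, expected):
        t = RampTest([0, 1, 2], [0, 1, 2], diameter_um=d, gauge_length_mm=20)
        ok, _ = qc_filter(t)
        assert ok is expected

    def test_failed_qc_summary_is_nan(self):
        s = analyze_ramp(RampTest([0, 1, 2], [0, 1, 2], diameter_um=50.0,
                                  gauge_length_mm=20))
        assert not s.qc_pass and np.isnan(s.E_MPa)


class TestPreload:
    def test_linear_interpolated_crossing(self):
        t = RampTest([0.0, 0.1, 0.2], [0.01, 0.02, 0.03], diameter_um=350,
                     gauge_length_mm=20)
        assert preload_offset(t) == pytest.approx(0.05)

    def test_starts_above_preload_warns(self):
        t = RampTest([0.0, 0.1, 0.2], [0.02, 0.03, 0.04], diameter_um=350,
                     gauge_length_mm=20)
        with pytest.warns(UserWarning, match="above preload"):
            assert preload_offset(t) == 0.0

    def test_never_reaches_preload_rejected(self):
        t = RampTest([0.0, 0.1, 0.2], [0.001, 0.002, 0.003], diameter_um=350,
                     gauge_length_mm=20)
        with pytest.raises(InputError, match="never reaches preload"):
            preload_offset(t)

    def test_toe_curve_closed_form_crossing(self):
        test, truth = simulate_tensile(600.0, noise_frac=0.0)
        spacing = np.diff(test.displacement_mm).mean()
        assert preload_offset(test) == pytest.approx(
            truth["preload_displacement_mm"], abs=spacing / 10.0)


class TestStressStrain:
    def test_csa_closed_form(self):
        t = RampTest([0, 1, 2], [0, 1, 2], diameter_um=1000.0, gauge_length_mm=20)
        assert t.csa_mm2 == pytest.approx(math.pi / 4.0)

    def test_stress_units(self):
        t = RampTest([0, 1, 2], [0.0, 0.5, 1.0], diameter_um=1000.0,
                     gauge_length_mm=20)
        _, stress = stress_strain(t, 0.0)
        assert stress[-1] == pytest.approx(1.0 / (math.pi / 4.0))  # 1.273 MPa

    def test_full_record_matches_generator_model(self):
        """Noiseless synthetic record vs the toe+linear model re-evaluated
        independently at the sampled strains."""
        E, toe, B = 600.0, 0.004, 200.0
        test, truth = simulate_tensile(E, toe_strain=toe, toe_B=B,
                                       noise_frac=0.0)
        strain, stress = stress_strain(test, 0.0)  # generator strain origin
        A = E / (B * math.exp(B * toe))
        sigma_toe = A * (math.exp(B * toe) - 1.0)
        in_toe = strain <= toe
        linear = (strain > toe) & (strain <= truth["failure_strain"])
        expect = np.where(in_toe, A * (np.exp(B * np.minimum(strain, toe)) - 1.0),
                          sigma_toe + E * (strain - toe))
        err = np.abs(stress[in_toe | linear] - expect[in_toe | linear])
        assert err.max() < 1e-9


class TestTangentModulus:
    def test_linear_material_exact(self):
        strain = np.linspace(0, 0.02, 200)
        assert tangent_modulus(strain, 600.0 * strain) == pytest.approx(600.0)

    def test_toe_model_matches_normal_equations(self):
        strain = np.linspace(0, 0.02, 400)
        stress = 1.3 * (np.exp(180.0 * strain) - 1.0)
        window = (0.005, 0.010)
        sel = (strain >= window[0]) & (strain <= window[1])
        slope, _ = normal_equations_slope(strain[sel], stress[sel])
        assert tangent_modulus(strain, stress, window) == pytest.approx(slope)

    def test_insufficient_window_samples_rejected(self):
        strain = np.array([0.0, 0.004, 0.02])
        with pytest.raises(InputError, match="samples inside"):
            tangent_modulus(strain, strain * 600)


class TestFailure:
    def test_triangular_peak(self):
        d = np.linspace(0, 2, 201)
        f = np.where(d <= 1.0, 2.0 * d, 2.0 * (2.0 - d))
        t = RampTest(d, f, diameter_um=350, gauge_length_mm=20)
        fm = failure_metrics(t, 0.0, window=(0.005, 0.02))
        assert fm["failure_force_N"] == pytest.approx(2.0)
        assert not fm["no_failure_detected"]

    def test_linear_stiffness_exact(self):
        d = np.linspace(0, 1, 200)
        t = RampTest(d, 10.0 * d, diameter_um=350, gauge_length_mm=20)
        fm = failure_metrics(t, 0.0, window=(0.005, 0.02))
        assert fm["stiffness_N_mm"] == pytest.approx(10.0)
        assert fm["no_failure_detected"]  # rises to the end of the record

    def test_generator_failure_point(self):
        test, truth = simulate_tensile(600.0, noise_frac=0.0)
        off = preload_offset(test)
        fm = failure_metrics(test, off)
        strain_spacing = np.diff(test.displacement_mm).mean() / test.gauge_length_mm
        eps_fail_meas = truth["failure_strain"] - off / test.gauge_length_mm
        assert fm["failure_strain"] == pytest.approx(eps_fail_meas,
                                                     abs=1.5 * strain_spacing)


class TestInvariants:
    def test_stiffness_modulus_consistency_on_linear_record(self):
        t = linear_ramp()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = analyze_ramp(t, preload_N=1e-6)
        assert s.E_MPa * s.csa_mm2 / t.gauge_length_mm == pytest.approx(
            s.stiffness_N_mm, rel=1e-6)

    def test_force_scale_equivariance(self):
        test, _ = simulate_tensile(600.0, noise_frac=0.0)
        doubled = RampTest(test.displacement_mm, 2.0 * test.force_N,
                           diameter_um=test.diameter_um,
                           gauge_length_mm=test.gauge_length_mm)
        s1, s2 = analyze_ramp(test), analyze_ramp(doubled, preload_N=0.03)
        assert s2.E_MPa == pytest.approx(2.0 * s1.E_MPa, rel=1e-9)
        assert s2.failure_force_N == pytest.approx(2.0 * s1.failure_force_N)
        assert s2.failure_strain == pytest.approx(s1.failure_strain, abs=1e-12)

    def test_modulus_recovery_bias_under_dispersion(self):
        """200 seeded fascicles, lognormal modulus dispersion, 1% force noise:
        mean bias of the recovered modulus < 1%."""
        wt, _, truth = simulate_tensile_cohorts(
            600.0, 0.0, n_per_group=200, dispersion_cv=0.15, seed=42)
        Es = [analyze_ramp(t).E_MPa for t in wt]
        assert np.mean(Es) == pytest.approx(truth["E_wt_MPa"], rel=0.01)


class TestRampSegmentation:
    def test_preconditioning_cycles_stripped(self):
        up = np.linspace(0, 0.2, 21)
        cycle = np.concatenate([up, up[::-1][1:]])
        d = np.concatenate([cycle, cycle, np.linspace(0, 4.0, 200)])
        f = 0.1 * d
        ramp_d, ramp_f = final_ramp_segment(d, f)
        assert np.all(np.diff(ramp_d) >= 0)
        # the final monotone segment spans the full failure ramp (the cycle's
        # terminal sample may be retained as a leading duplicate)
        assert ramp_d[0] == 0.0 and ramp_d[-1] == 4.0
        assert len(ramp_d) in (200, 201)
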