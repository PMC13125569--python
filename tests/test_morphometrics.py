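"""FFT orientation, nuclear circularity and intensity quantification."""

import math

import numpy as np
import pytest
from scipy import ndimage
from skimage.draw import disk

from microtension.errors import InputError
from microtension.morphometrics import (fit_circularity_histogram,
                                        intensity_quantify,
                                        nuclear_circularity,
                                        orientation_distribution)
from microtension.synth import simulate_nuclei, simulate_texture


def angdiff(a, b):
    """Smallest difference between two orientations on [0, 180)."""
    d = (a - b) % 180.0
    return min(d, 180.0 - d)


class TestOrientation:
    @pytest.mark.parametrize("theta", [0.0, 30.0, 75.0, 120.0, 179.0])
    def test_grating_angle_recovered(self, theta):
        img, truth = simulate_texture(theta)
        od = orientation_distribution(img)
        assert angdiff(od.principal_angle_deg, truth["theta_deg"]) < 2.0
        assert od.alignment_index > 0.9

    def test_isotropic_noise_low_alignment(self):
        """99th percentile of the alignment index over 500 white-noise seeds."""
        ais = []
        for seed in range(500):
            rng = np.random.default_rng(seed)
            od = orientation_distribution(rng.normal(size=(128, 128)))
            ais.append(od.alignment_index)
        assert np.quantile(ais, 0.99) < 0.1

    def test_rotation_equivariance(self):
        img, _ = simulate_texture(30.0, shape=(384, 384))
        rot = ndimage.rotate(img, 45.0, reshape=False, mode="reflect")
        crop = (slice(64, -64), slice(64, -64))
        a0 = orientation_distribution(img[crop]).principal_angle_deg
        a1 = orientation_distribution(rot[crop]).principal_angle_deg
        assert angdiff(a1, (a0 + 45.0) % 180.0) < 2.0

    def test_weights_normalized_and_angle_in_range(self):
        img, _ = simulate_texture(100.0, coherence=0.7, seed=1)
        od = orientation_distribution(img)
        assert od.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(od.weights >= 0)
        assert 0.0 <= od.principal_angle_deg < 180.0

    def test_invariance_to_scaling_and_translation(self):
        img, _ = simulate_texture(42.0, coherence=0.9, seed=2)
        base = orientation_distribution(img)
        scaled = orientation_distribution(7.5 * img)
        rolled = orientation_distribution(np.roll(img, (13, 29), axis=(0, 1)))
        assert np.allclose(base.weights, scaled.weights, atol=1e-6)
        # circular shift perturbs only edge-window interactions
        assert angdiff(base.principal_angle_deg, rolled.principal_angle_deg) < 2.0

    def test_small_image_rejected(self):
        with pytest.raises(InputError):
            orientation_distribution(np.zeros((32, 32)))


class TestCircularity:
    def test_rasterized_circle_near_one(self):
        mask = np.zeros((128, 128), dtype=int)
        rr, cc = disk((64, 64), 50)
        mask[rr, cc] = 1
        res = nuclear_circularity(mask)
        assert res.per_object[0] >= 0.98

    def test_two_to_one_ellipse_closed_form(self):
        """Ellipse with a = 2b: 4πA/P² ≈ 0.84 via the Ramanujan perimeter."""
        mask, truth = simulate_nuclei(1, axis_ratio_mean=2.0,
                                      minor_axis_px=25.0, seed=0)
        res = nuclear_circularity(mask)
        assert truth.circularity[0] == pytest.approx(0.8412, abs=1e-3)
        assert res.per_object[0] == pytest.approx(truth.circularity[0], abs=0.03)

    def test_square_closed_form(self):
        mask = np.zeros((80, 80), dtype=int)
        mask[20:60, 20:60] = 1
        res = nuclear_circularity(mask)
        assert res.per_object[0] == pytest.approx(math.pi / 4.0, abs=0.03)

    def test_scale_invariance_across_resolution(self):
        """The same ellipse rasterized at 2× resolution scores within 0.02."""
        small, _ = simulate_nuclei(1, axis_ratio_mean=1.6, minor_axis_px=12.0,
                                   seed=3)
        big, _ = simulate_nuclei(1, axis_ratio_mean=1.6, minor_axis_px=24.0,
                                 seed=3)
        c1 = nuclear_circularity(small).per_object[0]
        c2 = nuclear_circularity(big).per_object[0]
        assert abs(c1 - c2) < 0.02

    def test_empty_mask_rejected(self):
        with pytest.raises(InputError):
            nuclear_circularity(np.zeros((50, 50), dtype=int))


class TestHistogramFit:
    def test_recovers_gaussian_parameters(self):
        rng = np.random.default_rng(7)
        values = np.clip(rng.normal(0.70, 0.05, 1000), 0.0, 1.0)
        fit = fit_circularity_histogram(values)
        assert fit["converged"]
        assert fit["mu"] == pytest.approx(0.70, abs=0.01)
        assert fit["sigma"] == pytest.approx(0.05, abs=0.01)

    def test_constant_values_degenerate(self):
        fit = fit_circularity_histogram(np.full(50, 0.8))
        assert fit["degenerate"] and fit["sigma"] == 0.0

    def test_amplitude_linearity(self):
        rng = np.random.default_rng(8)
        values = rng.normal(0.6, 0.08, 500)
        f1 = fit_circularity_histogram(values)
        f2 = fit_circularity_histogram(np.concatenate([values, values]))
        assert f2["amplitude"] == pytest.approx(2.0 * f1["amplitude"], rel=1e-6)
        assert f2["mu"] == pytest.approx(f1["mu"], abs=1e-9)
        assert f2["sigma"] == pytest.approx(f1["sigma"], abs=1e-9)

    def test_mu_error_shrinks_with_sample_size(self):
        errs = {n: [] for n in (100, 5000)}
        for seed in range(20):
            rng = np.random.default_rng(seed)
            for n in errs:
                values = rng.normal(0.7, 0.05, n)
                errs[n].append(abs(fit_circularity_histogram(values)["mu"] - 0.7))
        assert np.mean(errs[5000]) < np.mean(errs[100])

    def test_too_few_values_rejected(self):
        with pytest.raises(InputError):
            fit_circularity_histogram(np.ones(10))


class TestIntensity:
    def test_uniform_image_with_known_background(self):
        res = intensity_quantify({"g": [np.full((32, 32), 100.0)]},
                                 reference_group="g", background=10.0)
        assert res["g"]["mean"] == pytest.approx(90.0)

    def test_fifty_percent_increase_between_groups(self):
        lo = np.full((32, 32), 90.0)
        hi = np.full((32, 32), 135.0)
        res = intensity_quantify({"compliant": [lo], "rigid": [hi]},
                                 reference_group="compliant", background=0.0)
        assert res["rigid"]["fold_vs_reference"] == pytest.approx(1.5)

    def test_fold_invariant_to_global_scaling(self):
        rng = np.random.default_rng(5)
        imgs = {g: [rng.uniform(50, 200, (64, 64)) for _ in range(3)]
                for g in ("a", "b")}
        res1 = intensity_quantify(imgs, "a", background=0.0)
        res2 = intensity_quantify(
            {g: [3.0 * im for im in ims] for g, ims in imgs.items()},
            "a", background=0.0)
        assert res2["b"]["fold_vs_reference"] == pytest.approx(
            res1["b"]["fold_vs_reference"], rel=1e-9)

    def test_histogram_mode_background(self):
        img = np.full((64, 64), 20, dtype=np.uint8)
        img[:8, :8] = 200  # sparse bright foreground
        res = intensity_quantify({"g": [img]}, "g")
        expected = img.mean() - 20.0
        assert res["g"]["mean"] == pytest.approx(expected)

    def test_missing_reference_rejected(self):
        with pytest.raises(InputError):
            intensity_quantify({"a": [np.ones((8, 8))]}, reference_group="b")
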