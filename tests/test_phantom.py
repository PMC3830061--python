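"""Phantom generator tests: geometry against a brute-force oracle, analytic
deformation calibration against dense quadrature, and the corruption models.
"""

import numpy as np
import pytest

import jacint as J
from jacint.image import Labels


class TestMakePhantom:
    def test_geometry_matches_bruteforce_ellipsoids(self, phantom48):
        """Re-evaluate the nested-ellipsoid inequalities voxel by voxel."""
        spec, img, lab = phantom48
        grid = np.indices(spec.shape).reshape(3, -1).T.astype(float)
        world = grid * np.asarray(spec.spacing) + img.affine[:3, 3]
        c = img.center_world()
        b = spec.brain_semiaxes_mm()
        z = (world - c) / b
        r = np.sqrt((z ** 2).sum(axis=1))
        rv = np.sqrt(((z / spec.ventricle_frac) ** 2).sum(axis=1))
        expected = np.zeros(r.size, dtype=int)
        expected[r <= spec.skull_outer_frac] = Labels.SKULL
        expected[r <= spec.skull_inner_frac] = Labels.CSF
        expected[r <= 1.0] = Labels.GM
        expected[r <= spec.wm_frac] = Labels.WM
        expected[rv <= 1.0] = Labels.CSF
        assert np.array_equal(lab.data.ravel(), expected)

    def test_noise_free_intensities_exact(self, phantom48):
        spec, img, lab = phantom48
        gm = lab.mask(Labels.GM)
        assert np.all(img.data[gm] == spec.intensity_means[Labels.GM])

    def test_seeded_determinism(self):
        spec = J.PhantomSpec(shape=(32, 32, 32),
                             intensity_sds={Labels.CSF: 2, Labels.GM: 2,
                                            Labels.WM: 2, Labels.SKULL: 2},
                             seed=7)
        a, _ = J.make_phantom(spec)
        b, _ = J.make_phantom(spec)
        assert np.array_equal(a.data, b.data)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            J.PhantomSpec(spacing=(0.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            J.PhantomSpec(shape=(16, 16, 16))
        with pytest.raises(ValueError):
            J.PhantomSpec(intensity_means={Labels.CSF: 100.0, Labels.GM: 70.0,
                                           Labels.WM: 30.0, Labels.SKULL: 90.0})


class TestApplyAtrophy:
    def test_zero_change_is_identity(self, phantom48):
        spec, img, lab = phantom48
        fu, fwd, truth = J.apply_atrophy(img, lab, 0.0, "radial_gm", spec=spec)
        assert np.abs(fwd.vectors).max() == 0.0
        assert np.allclose(fu.data, img.data, atol=1e-3)

    def test_global_scale_detj_constant(self, phantom48):
        spec, img, lab = phantom48
        _, fwd, truth = J.apply_atrophy(img, lab, -1.0, "global_scale", spec=spec)
        dj = J.jacobian_determinant(fwd)
        interior = dj.data[1:-1, 1:-1, 1:-1]
        assert np.allclose(interior, 0.99, atol=1e-9)
        assert truth.true_pvc[Labels.GM] == pytest.approx(-1.0, abs=1e-9)

    def test_radial_calibration_dense_quadrature(self, atrophied64):
        """Analytic detJ integral over the GM mask hits the target PVC.

        The oracle re-integrates the closed-form determinant on a 2x
        oversampled quadrature grid restricted to the GM ellipsoid shell.
        """
        spec, img, lab, fu, fwd, truth = atrophied64
        p = truth.field_params
        # oversampled voxel-center quadrature inside the GM mask
        fine = J.make_grid(np.asarray(spec.shape) * 2, np.asarray(spec.spacing) / 2)
        detj = truth.detj(fine)
        c = fine.center_world()
        idx = np.indices(fine.shape).reshape(3, -1).T
        world = idx * fine.spacing + fine.affine[:3, 3]
        r = np.sqrt((((world - c) / p["semiaxes"]) ** 2).sum(axis=1))
        rv = np.sqrt((((world - c) / (p["semiaxes"] * spec.ventricle_frac)) ** 2).sum(axis=1))
        gm_fine = (r <= 1.0) & (r > spec.wm_frac) & (rv > 1.0)
        integral = detj.ravel()[gm_fine].mean()
        assert 100 * (integral - 1) == pytest.approx(-0.5, abs=0.05)

    def test_mode_and_range_validation(self, phantom48):
        spec, img, lab = phantom48
        with pytest.raises(ValueError):
            J.apply_atrophy(img, lab, -0.5, mode="shear")
        with pytest.raises(ValueError):
            J.apply_atrophy(img, lab, -60.0)


class TestBiasField:
    def test_zero_amplitude_identity(self, phantom48):
        _, img, _ = phantom48
        out = J.add_bias_field(img, 0.0, seed=1)
        assert np.array_equal(out.data, img.data)

    def test_ratio_equals_stored_field(self, phantom48):
        _, img, _ = phantom48
        out = J.add_bias_field(img, 0.1, scale_mm=30.0, seed=2)
        nz = img.data > 0
        assert np.allclose(out.data[nz] / img.data[nz], out.true_bias[nz],
                           rtol=1e-5)

    def test_seeds_decorrelated(self, phantom48):
        # a correlation length well below the FOV gives enough independent
        # patches for two seeds to decorrelate over the brain
        _, img, lab = phantom48
        a = J.add_bias_field(img, 0.1, scale_mm=10.0, seed=10).true_bias
        b = J.add_bias_field(img, 0.1, scale_mm=10.0, seed=11).true_bias
        brain = lab.brain_mask()
        r = np.corrcoef(np.log(a[brain]), np.log(b[brain]))[0, 1]
        assert abs(r) < 0.2


class TestNoise:
    def test_zero_sigma_identity(self, phantom48):
        _, img, _ = phantom48
        out = J.add_noise(img, 0.0)
        assert np.array_equal(out.data, img.data)

    def test_gaussian_sample_sd(self, phantom48):
        _, img, lab = phantom48
        out = J.add_noise(img, 5.0, "gaussian", seed=3)
        wm = lab.mask(Labels.WM)
        assert out.data[wm].std() == pytest.approx(5.0, rel=0.05)

    def test_rician_background_mean(self):
        zero = J.ImageVolume(np.zeros((40, 40, 40), np.float32), np.eye(4))
        out = J.add_noise(zero, 4.0, "rician", seed=4)
        assert out.data.mean() == pytest.approx(4.0 * np.sqrt(np.pi / 2), rel=0.02)


class TestLesions:
    def test_zero_lesions_identity(self, phantom48):
        _, img, lab = phantom48
        im2, lb2 = J.insert_lesions(img, lab, 0)
        assert np.array_equal(im2.data, img.data)
        assert np.array_equal(lb2.data, lab.data)

    def test_count_and_placement(self, phantom64):
        import scipy.ndimage as ndi
        _, img, lab = phantom64
        im2, lb2 = J.insert_lesions(img, lab, 5, (2.0, 3.5), 0.7, seed=6)
        lesions = lb2.mask(Labels.LESION)
        _, ncomp = ndi.label(lesions)
        assert ncomp == 5
        assert np.all(lab.mask(Labels.WM)[lesions])  # all inside former WM

    def test_hypointensity_factor(self, phantom64):
        spec, img, lab = phantom64
        im2, lb2 = J.insert_lesions(img, lab, 4, (2.0, 3.5), 0.7, seed=8)
        lesions = lb2.mask(Labels.LESION)
        ratio = im2.data[lesions].mean() / spec.intensity_means[Labels.WM]
        assert ratio == pytest.approx(0.7, abs=0.02)

    def test_impossible_placement_raises(self, phantom48):
        _, img, lab = phantom48
        with pytest.raises(RuntimeError):
            J.insert_lesions(img, lab, 500, (5.0, 6.0), 0.7, seed=1,
                             max_tries=5)


class TestDegradeResolution:
    def test_same_spacing_identity(self, phantom48):
        _, img, _ = phantom48
        out = J.degrade_resolution(img, img.spacing)
        assert np.array_equal(out.data, img.data)

    def test_extent_preserved_within_one_slab(self, phantom48):
        _, img, _ = phantom48
        out = J.degrade_resolution(img, (1.0, 1.0, 3.0))
        lo_i, hi_i = img.world_extent()
        lo_o, hi_o = out.world_extent()
        assert abs((hi_o[2] - lo_o[2]) - (hi_i[2] - lo_i[2])) <= 3.0

    def test_constant_image_unchanged(self):
        vol = J.make_grid((32, 32, 32), (1, 1, 1))
        vol = vol.like(np.full(vol.shape, 7.0, np.float32))
        out = J.degrade_resolution(vol, (2.0, 2.0, 2.0))
        assert np.allclose(out.data, 7.0)

    def test_upsampling_rejected(self, phantom48):
        _, img, _ = phantom48
        with pytest.raises(ValueError):
            J.degrade_resolution(img, (0.5, 1.0, 1.0))
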