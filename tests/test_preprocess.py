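"""Intensity/mask conditioning tests: EM segmentation against phantom truth,
NAWM lesion filling statistics, differential correction recovery, FOV
matching and the polynomial bias surrogate.
"""

import numpy as np
import pytest

import jacint as J
from jacint.image import Labels
from jacint.preprocess import (differential_intensity_correction, fill_lesions,
                               match_fov, segment_tissues, simple_bias_correct,
                               union_lesion_masks)


@pytest.fixture(scope="module")
def noisy_phantom():
    spec = J.PhantomSpec(shape=(64, 64, 64), noise_sd=5.0, seed=21)
    img, lab = J.make_phantom(spec)
    img = J.add_noise(img, spec.noise_sd, seed=spec.seed)
    return spec, img, lab


class TestSegmentation:
    def test_noiseless_phantom_high_accuracy(self, phantom64):
        _, img, lab = phantom64
        brain = lab.brain_mask()
        seg, stats = segment_tissues(img, brain)
        agree = (seg.data[brain] == lab.data[brain]).mean()
        assert agree >= 0.995

    def test_class_means_near_generating_values(self, noisy_phantom):
        # noise SD is 5% of the WM mean here
        spec, img, lab = noisy_phantom
        seg, stats = segment_tissues(img, lab.brain_mask())
        for code in (Labels.CSF, Labels.GM, Labels.WM):
            assert stats.means[code] == pytest.approx(
                spec.intensity_means[code], rel=0.02)

    def test_invariant_to_affine_intensity_rescale(self, noisy_phantom):
        _, img, lab = noisy_phantom
        brain = lab.brain_mask()
        seg1, _ = segment_tissues(img, brain)
        seg2, _ = segment_tissues(img.like((1.7 * img.data + 40).astype(np.float32)),
                                  brain)
        assert (seg1.data[brain] == seg2.data[brain]).mean() > 0.999

    def test_empty_mask_rejected(self, phantom64):
        _, img, _ = phantom64
        with pytest.raises(ValueError):
            segment_tissues(img, np.zeros(img.shape, bool))


class TestLesionFilling:
    @pytest.fixture(scope="class")
    def lesioned(self):
        spec = J.PhantomSpec(shape=(64, 64, 64), noise_sd=2.0, seed=33)
        img, lab = J.make_phantom(spec)
        img = J.add_noise(img, spec.noise_sd, seed=40)
        img, lab = J.insert_lesions(img, lab, 6, (2.0, 4.0), 0.7, seed=41)
        return spec, img, lab

    def test_empty_mask_is_identity(self, phantom64):
        _, img, lab = phantom64
        _, stats = segment_tissues(img, lab.brain_mask())
        out = fill_lesions(img, np.zeros(img.shape, bool), stats)
        assert np.array_equal(out.data, img.data)

    def test_filled_mean_matches_nawm(self, lesioned):
        _, img, lab = lesioned
        lesions = lab.mask(Labels.LESION)
        _, stats = segment_tissues(img, lab.brain_mask(), lesion_mask=lesions)
        out = fill_lesions(img, lesions, stats, seed=1)
        n = lesions.sum()
        se = stats.nawm_sd / np.sqrt(n)
        assert abs(out.data[lesions].mean() - stats.nawm_mean) < 3 * se

    def test_filled_voxels_same_distribution_as_nawm(self, lesioned):
        from scipy import stats as sstats
        _, img, lab = lesioned
        lesions = lab.mask(Labels.LESION)
        nawm = lab.mask(Labels.WM)
        _, st = segment_tissues(img, lab.brain_mask(), lesion_mask=lesions)
        ts = []
        for seed in range(8):
            out = fill_lesions(img, lesions, st, seed=seed)
            t, _ = sstats.ttest_ind(out.data[lesions], img.data[nawm])
            ts.append(t)
        assert abs(np.mean(ts)) < 1.0  # no systematic offset across seeds

    def test_fill_restores_segmentation_gm_volume(self, lesioned):
        """Lesion filling removes lesion contamination of the GM estimate."""
        spec, img, lab = lesioned
        clean, clean_lab = J.make_phantom(spec)
        clean = J.add_noise(clean, spec.noise_sd, seed=40)
        brain = lab.brain_mask()
        seg_clean, _ = segment_tissues(clean, brain)
        lesions = lab.mask(Labels.LESION)
        _, st = segment_tissues(img, brain, lesion_mask=lesions)
        filled = fill_lesions(img, lesions, st, seed=2)
        seg_filled, _ = segment_tissues(filled, brain)
        v_clean = seg_clean.mask(Labels.GM).sum()
        v_filled = seg_filled.mask(Labels.GM).sum()
        assert abs(v_filled - v_clean) / v_clean < 0.005


class TestUnionLesionMasks:
    def _mask(self, shape, slc):
        m = np.zeros(shape, np.int16)
        m[slc] = Labels.LESION
        return J.LabelMap(m, np.eye(4))

    def test_single_mask_identity(self):
        m = self._mask((20, 20, 20), np.s_[5:8, 5:8, 5:8])
        union, back = union_lesion_masks([m], [J.AffineTransform.identity()])
        assert np.array_equal(union.data > 0, m.data > 0)
        assert np.array_equal(back[0].data > 0, m.data > 0)

    def test_disjoint_masks_sum(self):
        a = self._mask((20, 20, 20), np.s_[2:4, 2:4, 2:4])
        b = self._mask((20, 20, 20), np.s_[10:13, 10:13, 10:13])
        I = J.AffineTransform.identity()
        union, _ = union_lesion_masks([a, b], [I, I])
        assert (union.data > 0).sum() == (a.data > 0).sum() + (b.data > 0).sum()

    def test_nested_masks_give_larger(self):
        a = self._mask((20, 20, 20), np.s_[5:10, 5:10, 5:10])
        b = self._mask((20, 20, 20), np.s_[6:8, 6:8, 6:8])
        I = J.AffineTransform.identity()
        union, _ = union_lesion_masks([a, b], [I, I])
        assert np.array_equal(union.data > 0, a.data > 0)


class TestDifferentialCorrection:
    def test_identity_when_image_equals_template(self, phantom64):
        _, img, _ = phantom64
        out = differential_intensity_correction(img, img, 8.0)
        assert np.allclose(out.data, img.data, rtol=1e-5)
        assert np.allclose(out.bias, 1.0)

    def test_recovers_smooth_synthetic_bias(self, phantom64):
        _, img, lab = phantom64
        biased = J.add_bias_field(img, 0.05, scale_mm=40.0, seed=5)
        out = differential_intensity_correction(biased, img, 8.0)
        brain = lab.brain_mask()
        ratio = out.data[brain] / np.maximum(img.data[brain], 1e-6)
        assert np.sqrt(np.mean((ratio - 1.0) ** 2)) < 0.01

    def test_impulse_survives_median(self, phantom64):
        _, img, lab = phantom64
        data = img.data.copy()
        c = tuple(s // 2 for s in img.shape)
        data[c] *= 1.5  # isolated focal change
        spiked = img.like(data)
        out = differential_intensity_correction(spiked, img, 8.0)
        assert out.bias[c] == pytest.approx(1.0, abs=0.01)
        assert out.data[c] == pytest.approx(data[c], rel=0.02)

    def test_idempotent_within_one_percent(self, phantom64):
        _, img, lab = phantom64
        biased = J.add_bias_field(img, 0.05, scale_mm=40.0, seed=6)
        once = differential_intensity_correction(biased, img, 8.0)
        twice = differential_intensity_correction(once, img, 8.0)
        brain = lab.brain_mask()
        rel = (twice.data[brain] - once.data[brain]) / np.maximum(once.data[brain], 1e-6)
        assert np.sqrt(np.mean(rel ** 2)) < 0.01

    def test_subvoxel_kernel_rejected(self, phantom64):
        _, img, _ = phantom64
        with pytest.raises(ValueError):
            differential_intensity_correction(img, img, 0.4)


class TestMatchFov:
    def test_all_valid_unchanged(self, phantom48):
        _, img, _ = phantom48
        outs = match_fov([img.copy(), img.copy()])
        for o in outs:
            assert np.array_equal(o.data, img.data)

    def test_missing_slab_removed_everywhere(self, phantom48):
        _, img, _ = phantom48
        a = img.copy()
        valid = np.ones(img.shape, bool)
        valid[:, :, -10:] = False
        b = J.ImageVolume(img.data.copy(), img.affine.copy(), valid)
        outs = match_fov([a, b])
        for o in outs:
            assert np.all(o.data[:, :, -10:] == 0)
            assert not o.valid[:, :, -10:].any()

    def test_intersection_count(self, phantom48):
        _, img, _ = phantom48
        v1 = np.ones(img.shape, bool); v1[:5] = False
        v2 = np.ones(img.shape, bool); v2[..., :7] = False
        a = J.ImageVolume(img.data.copy(), img.affine.copy(), v1)
        b = J.ImageVolume(img.data.copy(), img.affine.copy(), v2)
        outs = match_fov([a, b])
        assert outs[0].valid.sum() == (v1 & v2).sum()

    def test_empty_intersection_raises(self, phantom48):
        _, img, _ = phantom48
        v1 = np.zeros(img.shape, bool); v1[:10] = True
        v2 = np.zeros(img.shape, bool); v2[-10:] = True
        a = J.ImageVolume(img.data.copy(), img.affine.copy(), v1)
        b = J.ImageVolume(img.data.copy(), img.affine.copy(), v2)
        with pytest.raises(ValueError):
            match_fov([a, b])


class TestSimpleBiasCorrect:
    def test_bias_free_nearly_unchanged(self, noisy_phantom):
        _, img, lab = noisy_phantom
        brain = lab.brain_mask()
        out = simple_bias_correct(img, brain)
        rel = (out.data[brain] - img.data[brain]) / np.maximum(img.data[brain], 1)
        assert np.sqrt(np.mean(rel ** 2)) < 0.01

    def test_polynomial_bias_recovered(self, noisy_phantom):
        _, img, lab = noisy_phantom
        brain = lab.brain_mask()
        x = np.linspace(-1, 1, img.shape[0])
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        bias = np.exp(0.06 * X - 0.05 * Y * Z + 0.04 * Z ** 2).astype(np.float32)
        biased = img.like(img.data * bias)
        out = simple_bias_correct(biased, brain)
        ratio = out.data[brain] / np.maximum(img.data[brain], 1e-6)
        ratio /= ratio.mean()
        assert np.sqrt(np.mean((ratio - 1) ** 2)) < 0.02

    def test_brain_mean_preserved(self, noisy_phantom):
        _, img, lab = noisy_phantom
        brain = lab.brain_mask()
        out = simple_bias_correct(img, brain)
        assert out.data[brain].mean() == pytest.approx(img.data[brain].mean(),
                                                       rel=1e-4)
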