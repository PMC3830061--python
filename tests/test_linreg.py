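"""Affine machinery tests: NMI properties against a hand-rolled histogram
oracle, closed-form matrix identities, resampling contracts, and recovery of
known synthetic transforms.
"""

import numpy as np
import pytest

import jacint as J
from jacint.linreg import (AffineTransform, concatenate, halfway_decompose,
                           make_affine, make_grid, matrix_average, nmi,
                           pairreg_like, resample)


def reference_nmi(x, y, bins):
    """Independent joint-histogram entropy computation."""
    h, _, _ = np.histogram2d(x, y, bins=bins)
    p = h / h.sum()

    def ent(q):
        q = q[q > 0]
        return -(q * np.log(q)).sum()

    return (ent(p.sum(1)) + ent(p.sum(0))) / ent(p.ravel())


class TestNMI:
    def test_self_similarity_is_maximal(self, phantom48, rng):
        _, img, _ = phantom48
        other = img.like(rng.normal(50, 10, img.shape).astype(np.float32))
        assert nmi(img, img) >= nmi(img, other)

    def test_invariant_to_monotone_remap(self, phantom48):
        _, img, _ = phantom48
        remapped = img.like((2.5 * img.data + 17.0).astype(np.float32))
        assert nmi(img, img) == pytest.approx(nmi(img, remapped), abs=1e-9)

    def test_matches_reference_histogram_oracle(self, rng):
        a = rng.normal(0, 1, (24, 24, 24)).astype(np.float32)
        b = rng.normal(0, 1, (24, 24, 24)).astype(np.float32)
        va = J.ImageVolume(a, np.eye(4))
        vb = J.ImageVolume(b, np.eye(4))
        got = nmi(va, vb, bins=32)
        want = reference_nmi(a.ravel(), b.ravel(), 32)
        assert got == pytest.approx(want, rel=0.02)

    def test_empty_overlap_raises(self, phantom48):
        _, img, _ = phantom48
        masked = img.like(img.data.copy(), valid=np.zeros(img.shape, bool))
        with pytest.raises(ValueError):
            nmi(masked, masked)


class TestAffineAlgebra:
    def test_concatenate_identity_and_det(self):
        a = make_affine(rot=(0.1, 0, 0.05), scale=1.1, trans=(2, 1, -3))
        assert np.allclose(concatenate(AffineTransform.identity(), a).matrix,
                           a.matrix)
        b = make_affine(scale=(1.2, 0.9, 1.05))
        assert np.linalg.det(concatenate(a, b).matrix[:3, :3]) == pytest.approx(
            a.det3() * b.det3())

    def test_concatenate_point_mapping(self, rng):
        a = make_affine(rot=(0.05, -0.02, 0.1), trans=(1, 2, 3))
        b = make_affine(scale=1.05, trans=(-2, 0, 1))
        pts = rng.normal(0, 10, (5, 3))
        assert np.allclose(concatenate(a, b).apply(pts), a.apply(b.apply(pts)))

    def test_matrix_average_identities(self):
        I = AffineTransform.identity()
        assert np.allclose(matrix_average([I, I]).matrix, np.eye(4))
        a = make_affine(rot=(0.1, 0.05, -0.08), scale=1.1, trans=(3, -1, 2))
        avg = matrix_average([a, a.inverse()])
        assert np.allclose(avg.matrix, np.eye(4), atol=1e-8)

    def test_matrix_average_commuting_scales_geometric_mean(self):
        s1 = make_affine(scale=1.2)
        s2 = make_affine(scale=1.25)
        avg = matrix_average([s1, s2])
        assert avg.matrix[0, 0] == pytest.approx(np.sqrt(1.2 * 1.25), abs=1e-10)

    def test_matrix_average_rejects_negative_det(self):
        bad = np.diag([-1.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            AffineTransform(bad)

    def test_subject_template_unbiased(self, rng):
        """The log-Euclidean template of all pairwise transforms privileges
        no time-point: the matrix-logs of the per-time-point template
        transforms sum to zero."""
        import scipy.linalg
        to_t0 = [AffineTransform.identity()] + [
            make_affine(rot=rng.normal(0, 0.02, 3),
                        scale=1 + rng.normal(0, 0.01),
                        trans=rng.normal(0, 1, 3)) for _ in range(2)]
        n = len(to_t0)
        to_template = []
        for i in range(n):
            pairwise = [concatenate(to_t0[j].inverse(), to_t0[i]) for j in range(n)]
            to_template.append(matrix_average(pairwise))
        total = sum(scipy.linalg.logm(t.matrix).real for t in to_template)
        assert np.abs(total).max() < 1e-6

    def test_halfway_scale(self):
        a = make_affine(scale=1.21)
        hb, hf = halfway_decompose(a)
        assert hf.matrix[0, 0] == pytest.approx(1.1, abs=1e-12)

    def test_halfway_identity(self):
        hb, hf = halfway_decompose(AffineTransform.identity())
        assert np.allclose(hb.matrix, np.eye(4))
        assert np.allclose(hf.matrix, np.eye(4))

    def test_halfway_recomposition_random_small_affine(self, rng):
        for _ in range(5):
            a = make_affine(rot=rng.normal(0, 0.05, 3),
                            scale=1 + rng.normal(0, 0.02),
                            shear=rng.normal(0, 0.01, 3),
                            trans=rng.normal(0, 2, 3))
            hb, hf = halfway_decompose(a)
            # each image travels half: h_f^-1 . h_b == a^-1
            recomp = np.linalg.inv(hf.matrix) @ hb.matrix
            assert np.allclose(recomp, np.linalg.inv(a.matrix), atol=1e-10)

    def test_ascii_round_trip(self, tmp_path):
        a = make_affine(rot=(0.02, -0.01, 0.3), scale=1.07, trans=(1.5, -2, 0.25))
        p = tmp_path / "t.mat"
        a.save(p)
        b = AffineTransform.load(p)
        assert np.allclose(a.matrix, b.matrix, atol=1e-15)


class TestResample:
    def test_identity_nearest_bit_identical(self, phantom48):
        _, img, _ = phantom48
        out = resample(img, None, img, interp="nearest")
        assert np.array_equal(out.data, img.data)

    def test_constant_image_invariant(self):
        grid = make_grid((24, 24, 24), (1, 1, 1))
        vol = grid.like(np.full(grid.shape, 3.0, np.float32))
        t = make_affine(rot=(0.1, 0.2, -0.1), trans=(2, -1, 3))
        out = resample(vol, t, grid, interp="linear")
        inside = out.valid_mask()
        assert np.allclose(out.data[inside], 3.0, atol=1e-5)

    def test_ramp_shifted_by_one_voxel(self):
        grid = make_grid((24, 24, 24), (1, 1, 1))
        ramp = np.broadcast_to(np.arange(24, dtype=np.float32)[:, None, None],
                               (24, 24, 24)).copy()
        vol = grid.like(ramp)
        t = make_affine(trans=(1.0, 0, 0))  # one voxel along x (1 mm spacing)
        out = resample(vol, t, grid, interp="linear")
        # pull-back through a +1 mm translation samples the ramp at x-1
        assert np.allclose(out.data[2:-2, 2:-2, 2:-2],
                           ramp[2:-2, 2:-2, 2:-2] - 1.0, atol=1e-5)

    def test_singular_transform_rejected(self, phantom48):
        _, img, _ = phantom48
        with pytest.raises(ValueError):
            AffineTransform(np.diag([0.0, 1.0, 1.0, 1.0]))

    def test_windowed_sinc_identity_close(self, phantom48):
        _, img, _ = phantom48
        out = resample(img, None, img, interp="windowed_sinc")
        assert np.allclose(out.data, img.data, atol=1e-3)


class TestRegistrationRecovery:
    def test_identity_pair(self, phantom48):
        _, img, _ = phantom48
        t = J.hierarchical_affine(img, img)
        assert np.abs(t.matrix - np.eye(4)).max() < 1e-2

    def test_recovers_synthetic_similarity(self, phantom64):
        """Scale within 0.5%, shift within 0.5 mm on a noiseless phantom."""
        _, img, _ = phantom64
        true = make_affine(rot=(0, 0, np.deg2rad(4)), scale=1.02,
                           trans=(3.0, -2.0, 1.0), center=img.center_world())
        moved = resample(img, true, img, interp="windowed_sinc")
        moved.valid = None
        t = J.hierarchical_affine(moved, img)
        # recovered transform inverts the applied one
        resid = t.matrix @ true.matrix
        scale_err = abs(np.linalg.det(resid[:3, :3]) ** (1 / 3) - 1.0)
        assert scale_err < 0.005
        center = img.center_world()
        shift_err = np.abs(resid[:3, :3] @ center + resid[:3, 3] - center)
        assert np.all(shift_err < 0.75)

    def test_pairreg_absorbs_scanner_scale(self, phantom64):
        _, img, lab = phantom64
        mis, _ = J.apply_miscalibration(img, 1.01)
        a = pairreg_like(img, mis, lab.brain_mask(), lab.mask(J.Labels.SKULL))
        scale = a.det3() ** (-1 / 3)
        assert scale == pytest.approx(1.01, abs=0.002)

    def test_pairreg_rigid_fallback_without_skull(self, phantom64):
        _, img, lab = phantom64
        with pytest.warns(UserWarning):
            a = pairreg_like(img, img, lab.brain_mask(),
                             np.zeros(img.shape, bool))
        assert a.flags.get("rigid_only")
        assert np.abs(a.matrix - np.eye(4)).max() < 0.05

    def test_symmetry_rotation_on_symmetric_phantom(self, phantom48):
        _, img, _ = phantom48
        t = J.symmetry_rotation(img)
        angle = np.rad2deg(np.arccos(np.clip((np.trace(t.matrix[:3, :3]) - 1) / 2,
                                             -1, 1)))
        assert angle < 0.2

    def test_symmetry_rotation_recovers_known_rotation(self, phantom64):
        _, img, _ = phantom64
        rot = make_affine(rot=(0, 0, np.deg2rad(5)), center=img.center_world())
        rimg = resample(img, rot, img, interp="linear")
        rimg.valid = None
        t = J.symmetry_rotation(rimg)
        angle = np.rad2deg(np.arccos(np.clip((np.trace(t.matrix[:3, :3]) - 1) / 2,
                                             -1, 1)))
        assert angle == pytest.approx(5.0, abs=0.5)

    def test_symmetry_rotation_intensity_scale_invariant(self, phantom48):
        _, img, _ = phantom48
        t1 = J.symmetry_rotation(img)
        t2 = J.symmetry_rotation(img.like((3.0 * img.data).astype(np.float32)))
        assert np.allclose(t1.matrix, t2.matrix, atol=1e-6)
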