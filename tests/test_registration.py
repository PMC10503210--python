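"""Deformation fields, demons backend, QC metrics and their oracles."""

import numpy as np
import pytest
from scipy import ndimage

import wbatlas as w
from wbatlas.phantom import random_smooth_deformation
from wbatlas.volume import Volume

from conftest import make_textured_phantom


def _field(u, spacing=(1.0, 1.0, 1.0)):
    return w.DeformationField(displacement=np.asarray(u, float), spacing=spacing)


class TestApplyDeformation:
    def test_zero_field_is_identity(self):
        rng = np.random.default_rng(0)
        vol = Volume(values=rng.normal(size=(6, 6, 6)))
        out = w.apply_deformation(vol, w.DeformationField.zero(vol))
        np.testing.assert_allclose(out.values, vol.values)

    def test_integer_shift_nearest_is_exact(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(8, 8, 8))
        vol = Volume(values=vals, spacing=(2.0, 2.0, 2.0))
        u = np.zeros((3, 8, 8, 8))
        u[0] = 2.0  # +1 voxel in x (pull-back: out(x) = in(x + 1vox))
        out = np.asarray(
            w.apply_deformation(vol, _field(u, (2.0, 2.0, 2.0)), "nearest").values
        )
        np.testing.assert_array_equal(out[:-1], vals[1:])

    def test_nearest_preserves_binary_labels(self):
        rng = np.random.default_rng(2)
        vol = Volume(values=(rng.uniform(0, 1, (8, 8, 8)) > 0.5).astype(np.uint8))
        warp = random_smooth_deformation((8, 8, 8), (1, 1, 1), 1.5, rng=rng)
        out = np.asarray(w.apply_deformation(vol, warp, "nearest").values)
        assert set(np.unique(out)) <= {0, 1}

    def test_unknown_interpolation_rejected(self):
        vol = Volume(values=np.zeros((4, 4, 4)))
        with pytest.raises(ValueError):
            w.apply_deformation(vol, w.DeformationField.zero(vol), "cubic")

    def test_composition_consistency(self):
        rng = np.random.default_rng(3)
        vals = ndimage.gaussian_filter(rng.normal(size=(16, 16, 16)), 3) * 100
        vol = Volume(values=vals)
        f1 = random_smooth_deformation((16, 16, 16), (1, 1, 1), 0.8, smooth_mm=6, rng=rng)
        f2 = random_smooth_deformation((16, 16, 16), (1, 1, 1), 0.8, smooth_mm=6, rng=rng)
        two_step = w.apply_deformation(w.apply_deformation(vol, f1), f2)
        one_step = w.apply_deformation(vol, w.compose_fields(f1, f2))
        interior = (slice(3, -3),) * 3
        # double linear interpolation vs single: agreement within a small
        # fraction of the image standard deviation (~4)
        np.testing.assert_allclose(
            np.asarray(two_step.values)[interior],
            np.asarray(one_step.values)[interior],
            atol=0.25,
        )


class TestQCMetrics:
    def test_dice_hand_arithmetic(self):
        # |A| = 100, |B| = 50, overlap 50 -> 2*50/150
        a = np.zeros((10, 10, 2), bool)
        a[:5, :, :] = True  # 100 voxels
        b = np.zeros_like(a)
        b[:5, :5, :] = True  # 50 voxels, all inside A
        qc = w.qc_report(
            w.DeformationField.zero(Volume(values=a.astype(float))),
            Volume(values=a.astype(np.uint8)),
            Volume(values=b.astype(np.uint8)),
        )
        assert qc.mask_dice == pytest.approx(2 * 50 / 150)

    def test_identity_mask_gives_dice_one_and_no_folds(self):
        m = Volume(values=np.pad(np.ones((4, 4, 4)), 2).astype(np.uint8))
        qc = w.qc_report(w.DeformationField.zero(m), m, m)
        assert qc.mask_dice == 1.0
        assert qc.negative_jacobians == 0

    def test_both_masks_empty_is_error(self):
        m = Volume(values=np.zeros((4, 4, 4), dtype=np.uint8))
        with pytest.raises(ValueError):
            w.qc_report(w.DeformationField.zero(m), m, m)

    def test_uniform_contraction_has_positive_jacobian(self):
        # u = -0.2 * x (mm) -> det J = 0.8^3 > 0 everywhere
        shape = (8, 8, 8)
        idx = np.stack(np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij"))
        f = _field(-0.2 * idx)
        det = w.jacobian_determinant(f)
        np.testing.assert_allclose(det, 0.8**3, rtol=1e-6)
        m = Volume(values=np.pad(np.ones((4, 4, 4)), 2).astype(np.uint8))
        assert w.qc_report(f, m, m).negative_jacobians == 0

    def test_jacobian_matches_brute_force_loop(self):
        rng = np.random.default_rng(4)
        shape = (6, 7, 8)
        spacing = (2.0, 1.5, 3.0)
        f = random_smooth_deformation(shape, spacing, 2.0, smooth_mm=6, rng=rng)
        det = w.jacobian_determinant(f)
        u = f.displacement
        # oracle: explicit central/one-sided differences, voxel loop
        for p in [(2, 3, 4), (0, 0, 0), (5, 6, 7), (3, 1, 2)]:
            J = np.zeros((3, 3))
            for i in range(3):
                for j in range(3):
                    lo = list(p)
                    hi = list(p)
                    hi[j] = min(p[j] + 1, shape[j] - 1)
                    lo[j] = max(p[j] - 1, 0)
                    du = u[i][tuple(hi)] - u[i][tuple(lo)]
                    dx = (hi[j] - lo[j]) * spacing[j]
                    J[i, j] = du / dx + (1 if i == j else 0)
            assert det[p] == pytest.approx(np.linalg.det(J), rel=1e-9)

    def test_inverse_consistency_vme_zero_for_true_inverse_translation(self):
        shape = (10, 10, 10)
        m = Volume(values=np.pad(np.ones((6, 6, 6)), 2).astype(np.uint8))
        fwd = _field(np.stack([np.full(shape, 3.0), np.zeros(shape), np.zeros(shape)]))
        bwd = _field(np.stack([np.full(shape, -3.0), np.zeros(shape), np.zeros(shape)]))
        qc = w.qc_report(fwd, m, m, backward_field=bwd)
        assert qc.inverse_consistency_vme == pytest.approx(0.0, abs=1e-9)
        qc2 = w.qc_report(fwd, m, m, backward_field=fwd)
        assert qc2.inverse_consistency_vme == pytest.approx(6.0, rel=1e-9)


class TestDemonsPipeline:
    def test_self_registration_near_identity(self):
        fixed, body = make_textured_phantom()
        u = w.demons_register(
            [np.asarray(fixed.values)], [np.asarray(fixed.values)], fixed.spacing
        )
        f = w.DeformationField(displacement=u, spacing=fixed.spacing)
        assert f.magnitude()[body].mean() < min(fixed.spacing)
        det = w.jacobian_determinant(f)
        assert int((det <= 0).sum()) == 0

    def test_translation_recovery_within_one_voxel(self):
        fixed, body = make_textured_phantom()
        vals = np.asarray(fixed.values)
        shift_vox = 10.0 / fixed.spacing[0]
        moving = ndimage.shift(vals, (shift_vox, 0, 0), order=1)
        u = w.demons_register([vals], [moving], fixed.spacing)
        mean_ux = u[0][body].mean()
        assert abs(mean_ux - 10.0) < fixed.spacing[0]

    def test_smooth_warp_residual_reduced(self):
        fixed, body = make_textured_phantom()
        rng = np.random.default_rng(7)
        warp = random_smooth_deformation(
            fixed.shape, fixed.spacing, amplitude_mm=6.0, smooth_mm=25.0, rng=rng
        )
        moving = w.apply_deformation(fixed, warp)
        u = w.demons_register(
            [np.asarray(fixed.values)],
            [np.asarray(moving.values)],
            fixed.spacing,
            sigma_fluid_mm=6.0,
            sigma_diffusion_mm=6.0,
            iterations=(100, 80, 50),
        )
        g = w.DeformationField(displacement=u, spacing=fixed.spacing)
        residual = np.sqrt((w.compose_fields(warp, g).displacement ** 2).sum(0))
        reduction = 1.0 - residual[body].mean() / warp.magnitude()[body].mean()
        assert reduction >= 0.60

    def test_pre_register_improves_dice_and_signals_failure(self, noisy_subject):
        ms = w.make_mask_set(noisy_subject.water, noisy_subject.fat)
        # shifted copy of the same subject as "moving"
        shift = 2
        mb = np.roll(np.asarray(ms.body.values), shift, axis=0)
        mi = np.roll(np.asarray(ms.inside_sat.values), shift, axis=0)
        md = np.roll(np.asarray(ms.dilated_body.values), shift, axis=0)
        moving = w.MaskSet(
            body=ms.body.with_values(mb),
            inside_sat=ms.inside_sat.with_values(mi),
            dilated_body=ms.dilated_body.with_values(md),
        )
        f = w.pre_register(ms, moving)
        qc = w.qc_report(f, ms.body, moving.body)
        base = w.qc_report(w.DeformationField.zero(ms.body), ms.body, moving.body)
        assert qc.mask_dice >= base.mask_dice

        empty = w.MaskSet(
            body=ms.body.with_values(np.zeros_like(np.asarray(ms.body.values))),
            inside_sat=ms.inside_sat.with_values(np.zeros_like(mi)),
            dilated_body=ms.dilated_body.with_values(np.zeros_like(md)),
        )
        with pytest.raises(w.RegistrationError):
            w.pre_register(ms, empty)

    def test_main_registration_weight_map_stiffens_lean_tissue(self):
        fixed, body = make_textured_phantom(shape=(24, 24, 24))
        rng = np.random.default_rng(11)
        warp = random_smooth_deformation(fixed.shape, fixed.spacing, 4.0, smooth_mm=20, rng=rng)
        moving = w.apply_deformation(fixed, warp)
        wf = Volume(values=body.astype(float), spacing=fixed.spacing)
        ff = Volume(values=np.zeros(fixed.shape), spacing=fixed.spacing)

        def div_mag(w_lean):
            wmap = w.regularization_weight_map(wf, ff, w_lean=w_lean, w_fat=0.2)
            f = w.register_main(fixed, fixed, moving, moving, weight_map=wmap)
            grads = [np.gradient(f.displacement[i], *fixed.spacing)[i] for i in range(3)]
            return np.abs(sum(grads))[body].mean()

        assert div_mag(3.0) <= div_mag(1.0) + 1e-9

    def test_register_main_is_deterministic(self):
        fixed, _ = make_textured_phantom(shape=(16, 16, 16))
        moving = Volume(
            values=np.roll(np.asarray(fixed.values), 1, axis=1), spacing=fixed.spacing
        )
        f1 = w.register_main(fixed, fixed, moving, moving)
        f2 = w.register_main(fixed, fixed, moving, moving)
        np.testing.assert_array_equal(f1.displacement, f2.displacement)
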