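"""Registration: landmark similarity initialization, Mattes MI properties,
affine parameter recovery, diffeomorphic refinement and transform resampling."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from cnscoreg.core import Volume
from cnscoreg.register import (
    AffineTransform,
    DisplacementField,
    OverlapError,
    apply_transform,
    jacobian_determinant,
    landmark_init,
    mattes_mi,
    register_affine,
    register_diffeomorphic,
)
from cnscoreg.resample import antialias_downsample


@pytest.fixture(scope="module")
def brain_fixed_moving(brain_pair):
    fixed = antialias_downsample(brain_pair.high, brain_pair.low.spacing)
    return fixed, brain_pair.low


def corner_landmarks(vol: Volume, inset: float = 0.1) -> np.ndarray:
    ext = (np.array(vol.shape) - 1) * vol.spacing
    lo, hi = inset, 1 - inset
    return np.array(
        [[x * ext[0], y * ext[1], z * ext[2]]
         for x in (lo, hi) for y in (lo, hi) for z in (lo, hi)]
    )


class TestLandmarkInit:
    def test_identical_pairs_identity(self):
        pts = np.array([[0, 0, 0], [0, 0, 100.0]])
        t = landmark_init(pts, pts)
        np.testing.assert_allclose(t.matrix, np.eye(4), atol=1e-12)

    def test_pure_translation(self):
        f = np.array([[5, 5, 5], [5, 5, 105.0]])
        t = landmark_init(f, f + [10, 0, 0])
        np.testing.assert_allclose(t.matrix[:3, :3], np.eye(3), atol=1e-12)
        np.testing.assert_allclose(t.matrix[:3, 3], [10, 0, 0], atol=1e-12)

    def test_rotation_plus_scale_maps_endpoints_exactly(self):
        f = np.array([[0, 0, -50], [0, 0, 50.0]])     # along z, length 100
        m = np.array([[0, -100, 0], [0, 100, 0.0]])   # along y, length 200
        t = landmark_init(f, m, allow_scale=True)
        np.testing.assert_allclose(t.apply(f), m, atol=1e-9)

    def test_no_scale_keeps_lengths(self):
        f = np.array([[0, 0, 0], [0, 0, 100.0]])
        m = np.array([[0, 0, 0], [0, 0, 300.0]])
        t = landmark_init(f, m, allow_scale=False)
        moved = t.apply(f)
        assert np.linalg.norm(moved[1] - moved[0]) == pytest.approx(100.0)

    def test_zero_length_segment_rejected(self):
        p = np.array([[1, 1, 1], [1, 1, 1.0]])
        with pytest.raises(ValueError):
            landmark_init(p, np.array([[0, 0, 0], [0, 0, 9.0]]))


class TestMattesMI:
    def test_self_registration_beats_probe_perturbations(self, brain_fixed_moving):
        fixed, _ = brain_fixed_moving
        base = mattes_mi(fixed, fixed, AffineTransform.identity())
        rng = np.random.default_rng(42)
        center = fixed.index_to_world((np.array(fixed.shape) - 1) / 2)
        for _ in range(20):
            p = np.zeros(12)
            p[0:3] = rng.uniform(-0.05, 0.05, 3)      # up to ~3 degrees
            p[3:6] = rng.uniform(-250, 250, 3)        # up to 2 voxels
            p[6:9] = rng.uniform(-0.03, 0.03, 3)
            t = AffineTransform.from_params(p, center=center)
            assert base <= mattes_mi(fixed, fixed, t) + 1e-12

    def test_invariant_to_affine_intensity_map(self, brain_fixed_moving):
        fixed, _ = brain_fixed_moving
        rescaled = fixed.with_data(3.5 * fixed.data - 40.0)
        a = mattes_mi(fixed, fixed, AffineTransform.identity())
        b = mattes_mi(fixed, rescaled, AffineTransform.identity())
        assert abs(a - b) < 1e-3

    def test_independent_volumes_near_zero_bits(self):
        rng = np.random.default_rng(0)
        a = Volume(rng.random((32, 32, 32)))
        b = Volume(rng.random((32, 32, 32)))
        neg_mi = mattes_mi(a, b, AffineTransform.identity())
        assert -neg_mi < 0.05  # bits

    def test_insufficient_overlap_raises(self, brain_fixed_moving):
        fixed, moving = brain_fixed_moving
        far = AffineTransform(np.array([
            [1, 0, 0, 1e6], [0, 1, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1.0]]))
        with pytest.raises(OverlapError):
            mattes_mi(fixed, moving, far)

    def test_cross_check_against_simpleitk(self, brain_fixed_moving):
        """Independent oracle: SimpleITK's Mattes implementation must agree
        on the *ranking* of aligned vs misaligned poses."""
        sitk = pytest.importorskip("SimpleITK")
        fixed, _ = brain_fixed_moving
        img = sitk.GetImageFromArray(np.ascontiguousarray(fixed.data.T))
        img.SetSpacing(tuple(float(s) for s in fixed.spacing))
        img = sitk.Cast(img, sitk.sitkFloat64)

        def sitk_mi(shift_um):
            reg = sitk.ImageRegistrationMethod()
            reg.SetMetricAsMattesMutualInformation(32)
            reg.SetInitialTransform(sitk.TranslationTransform(3, (shift_um, 0.0, 0.0)))
            reg.SetInterpolator(sitk.sitkLinear)
            return reg.MetricEvaluate(img, img)

        def ours_mi(shift_um):
            m = np.eye(4)
            m[0, 3] = shift_um
            return mattes_mi(fixed, fixed, AffineTransform(m))

        shifts = [0.0, 1.5 * float(fixed.spacing[0]), 3.0 * float(fixed.spacing[0])]
        ours = [ours_mi(s) for s in shifts]
        theirs = [sitk_mi(s) for s in shifts]
        # both implementations must rank the poses identically (lower = better)
        assert ours == sorted(ours) and theirs == sorted(theirs)


class TestRegisterAffine:
    def test_self_registration_recovers_identity(self, brain_fixed_moving):
        fixed, _ = brain_fixed_moving
        res = register_affine(fixed, fixed, levels=2, iters_per_level=40, seed=0)
        center = fixed.index_to_world((np.array(fixed.shape) - 1) / 2)
        drift = np.linalg.norm(res.transform.apply(center) - center)
        assert drift <= 0.2 * float(min(fixed.spacing))

    def test_recovers_known_similarity(self, brain_pair, brain_fixed_moving):
        fixed, moving = brain_fixed_moving
        init = landmark_init(brain_pair.truth.landmarks_high, brain_pair.truth.landmarks_low)
        res = register_affine(fixed, moving, init=init, seed=1)
        assert res.converged
        true_fm = np.linalg.inv(brain_pair.truth.transform.affine)
        corners = corner_landmarks(brain_pair.high)
        est = res.transform.apply(corners)
        tru = corners @ true_fm[:3, :3].T + true_fm[:3, 3]
        tre = np.linalg.norm(est - tru, axis=1).max()
        assert tre <= float(min(moving.spacing))  # one low-res voxel

    def test_gross_initialization_propagates_overlap_error(self, brain_fixed_moving):
        fixed, moving = brain_fixed_moving
        bad = AffineTransform(np.array([
            [1, 0, 0, 5e5], [0, 1, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1.0]]))
        with pytest.raises(OverlapError):
            register_affine(fixed, moving, init=bad, levels=1, iters_per_level=5)

    def test_metric_trace_recorded_every_iteration(self, brain_fixed_moving):
        fixed, _ = brain_fixed_moving
        res = register_affine(fixed, fixed, levels=2, iters_per_level=10, seed=0)
        assert len(res.trace) >= 2
        levels = {l for (l, _, _) in res.trace}
        assert levels == {0, 1}


class TestAffineTransformAlgebra:
    def test_inverse_round_trip(self):
        p = np.array([0.1, -0.2, 0.05, 30, -10, 5, 0.05, -0.02, 0.01, 0.02, 0.0, -0.03])
        t = AffineTransform.from_params(p, center=np.array([10.0, 20, 30]))
        round_trip = t.compose(t.inverse()).matrix
        np.testing.assert_allclose(round_trip, np.eye(4), atol=1e-9)

    def test_composition_matches_sequential_application(self):
        rng = np.random.default_rng(1)
        a = AffineTransform.from_params(rng.normal(0, 0.05, 12))
        b = AffineTransform.from_params(rng.normal(0, 0.05, 12))
        pts = rng.uniform(-50, 50, (10, 3))
        np.testing.assert_allclose(b.compose(a).apply(pts), b.apply(a.apply(pts)), atol=1e-9)

    def test_singular_matrix_rejected(self):
        m = np.eye(4)
        m[0, 0] = 0.0
        with pytest.raises(ValueError):
            AffineTransform(m)


class TestApplyTransform:
    def test_identity_is_lossless(self):
        rng = np.random.default_rng(2)
        v = Volume(rng.random((10, 10, 10)), spacing=2.0)
        out = apply_transform(v, AffineTransform.identity(), target_grid=v)
        np.testing.assert_allclose(out.data, v.data, atol=1e-12)

    def test_one_voxel_translation_shifts_array(self):
        rng = np.random.default_rng(3)
        v = Volume(rng.random((12, 12, 12)), spacing=5.0)
        t = AffineTransform(np.array([
            [1, 0, 0, 5.0], [0, 1, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1.0]]))
        out = apply_transform(v, t, target_grid=v)
        np.testing.assert_allclose(out.data[:-1], v.data[1:], atol=1e-12)

    def test_chain_equals_composed_matrix(self):
        rng = np.random.default_rng(4)
        v = Volume(rng.random((16, 16, 16)), spacing=2.0)
        a = AffineTransform.from_params(
            np.array([0.02, 0, 0, 3, 1, 0, 0, 0, 0, 0, 0, 0]), center=np.full(3, 15.0))
        b = AffineTransform.from_params(
            np.array([0, 0.01, 0, -2, 0, 1, 0, 0, 0, 0, 0, 0]), center=np.full(3, 15.0))
        chained = apply_transform(v, [a, b], target_grid=v)
        composed = apply_transform(v, b.compose(a), target_grid=v)
        np.testing.assert_allclose(chained.data[2:-2, 2:-2, 2:-2],
                                   composed.data[2:-2, 2:-2, 2:-2], atol=1e-6)


class TestJacobianDeterminant:
    def _field(self, u, spacing=2.0):
        return DisplacementField(u, spacing=np.full(3, spacing), origin=np.zeros(3))

    def test_zero_field_unit_determinant(self):
        jd = jacobian_determinant(self._field(np.zeros((8, 8, 8, 3))))
        np.testing.assert_allclose(jd.data, 1.0)

    def test_uniform_linear_field(self):
        x = np.arange(8) * 2.0
        u = np.zeros((8, 8, 8, 3))
        u[..., 0] = 0.1 * x[:, None, None]
        jd = jacobian_determinant(self._field(u))
        np.testing.assert_allclose(jd.data[1:-1], 1.1, atol=1e-9)

    def test_small_rotation_field_near_unit(self):
        theta = 0.01
        x = (np.arange(10) - 4.5) * 2.0
        X, Y, _ = np.meshgrid(x, x, x, indexing="ij")
        u = np.zeros((10, 10, 10, 3))
        u[..., 0] = -theta * Y
        u[..., 1] = theta * X
        jd = jacobian_determinant(self._field(u))
        np.testing.assert_allclose(jd.data[1:-1, 1:-1, 1:-1], 1.0, atol=2 * theta**2 + 1e-9)


class TestRegisterDiffeomorphic:
    def test_identical_images_give_negligible_field(self, brain_fixed_moving):
        fixed, _ = brain_fixed_moving
        res = register_diffeomorphic(fixed, fixed, iters=20)
        assert res.converged
        assert np.abs(res.transform.field).max() <= 0.1 * float(min(fixed.spacing))

    def test_recovers_smooth_sinusoidal_warp(self, brain_fixed_moving):
        fixed, _ = brain_fixed_moving
        ext = (np.array(fixed.shape) - 1) * fixed.spacing
        X, Y, Z = np.meshgrid(*fixed.grid_world_coords(), indexing="ij")
        amp = 2.0 * float(min(fixed.spacing))
        ux = amp * np.sin(2 * np.pi * Z / ext[2]) * np.sin(np.pi * Y / ext[1])
        true_disp = np.stack([ux, np.zeros_like(ux), np.zeros_like(ux)], axis=-1)
        idx = np.indices(fixed.shape).astype(float)
        coords = [idx[a] + true_disp[..., a] / fixed.spacing[a] for a in range(3)]
        moving = fixed.with_data(ndi.map_coordinates(fixed.data, coords, order=1, mode="nearest"))
        res = register_diffeomorphic(fixed, moving)
        assert res.converged
        fg = fixed.data > 60
        err = np.linalg.norm(res.transform.field - (-true_disp), axis=-1)
        assert err[fg].mean() <= 0.75 * float(min(fixed.spacing))

    def test_accepted_field_has_positive_jacobian(self, brain_fixed_moving):
        fixed, _ = brain_fixed_moving
        rng = np.random.default_rng(5)
        moving = fixed.with_data(fixed.data + rng.normal(0, 2, fixed.shape))
        res = register_diffeomorphic(fixed, moving, iters=15)
        assert res.converged
        jd = jacobian_determinant(res.transform).data[1:-1, 1:-1, 1:-1]
        assert jd.min() > 0
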