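"""Groupwise rigid registration: template closed form, objective,
parameter recovery, gauge handling, mask robustness."""

import numpy as np
import pytest

import segmoco as sm
from segmoco.registration import (groupwise_objective, update_template,
                                  register_pairwise)


@pytest.fixture(scope="module")
def phantom48():
    return sm.make_phantom(48, seed=0)


@pytest.fixture(scope="module")
def known_motion_volumes(phantom32):
    """Segment volumes generated by applying known transforms (2-voxel /
    2-degree scale) to one clean phantom (coarse grid for speed)."""
    gt = sm.sample_random_trajectory(6, 2.0, 2.0, seed=3, n_shots=6)
    vols = [sm.apply_rigid(phantom32, s) for s in gt.states]
    mask = sm.make_registration_mask(phantom32, "full")
    return gt, vols, mask


@pytest.fixture(scope="module")
def known_motion_volumes64():
    """As above at 64^3, where interpolation bias is low enough for the
    0.2-voxel / 0.2-degree recovery contract."""
    x = sm.make_phantom(64, seed=0)
    gt = sm.sample_random_trajectory(8, 2.0, 2.0, seed=3, n_shots=8)
    vols = [sm.apply_rigid(x, s) for s in gt.states]
    mask = sm.make_registration_mask(x, "full")
    return gt, vols, mask


class TestUpdateTemplate:
    def test_identical_volumes_identity(self, phantom32):
        vols = [phantom32, phantom32]
        tpl = update_template([sm.IDENTITY, sm.IDENTITY], vols)
        assert np.abs(tpl.data - phantom32.data).max() < 1e-10

    def test_mean_of_two(self, phantom32):
        a = phantom32
        b = sm.Volume(a.data[::-1].copy())
        tpl = update_template([sm.IDENTITY, sm.IDENTITY], [a, b])
        assert np.abs(tpl.data - (a.data + b.data) / 2).max() < 1e-12

    def test_template_is_quadratic_minimizer(self, phantom32, rng):
        """Updating the template never increases the objective."""
        from conftest import random_transform
        vols = [sm.Volume(phantom32.data + 0.1 * rng.normal(size=phantom32.shape))
                for _ in range(3)]
        transforms = [random_transform(rng, trans=1, rot=2) for _ in range(3)]
        mask = np.ones(phantom32.shape, bool)
        arbitrary = sm.Volume(np.full(phantom32.shape, 0.3))
        before = groupwise_objective(transforms, vols, arbitrary, mask, 0.0)
        tpl = update_template(transforms, vols, mask)
        after = groupwise_objective(transforms, vols, tpl, mask, 0.0)
        assert after <= before + 1e-9


class TestObjective:
    def test_perfect_alignment_zero(self, phantom32):
        vols = [phantom32, phantom32]
        tpl = update_template([sm.IDENTITY] * 2, vols)
        val = groupwise_objective([sm.IDENTITY] * 2, vols, tpl,
                                  np.ones(phantom32.shape, bool), 0.0)
        assert val < 1e-18

    def test_matches_bruteforce_double_loop(self, rng):
        """At reg_weight 0 with identity transforms the objective equals
        the naive double sum over segments and voxels on an 8^3 image."""
        vols = [sm.Volume(rng.uniform(0, 1, (8, 8, 8))) for _ in range(3)]
        mask = rng.uniform(size=(8, 8, 8)) > 0.3
        transforms = [sm.IDENTITY] * 3
        tpl = update_template(transforms, vols, mask)
        got = groupwise_objective(transforms, vols, tpl, mask, 0.0)
        expected = 0.0
        for v in vols:
            for idx in np.argwhere(mask):
                i, j, k = idx
                expected += (v.data[i, j, k] - tpl.data[i, j, k]) ** 2
        assert got == pytest.approx(expected, rel=1e-10)

    def test_monotone_in_reg_weight(self, phantom32):
        vols = [phantom32, phantom32]
        tpl = update_template([sm.IDENTITY] * 2, vols)
        t = sm.RigidTransform(t=(1, 0, 0))
        mask = np.ones(phantom32.shape, bool)
        lo = groupwise_objective([t, t], vols, tpl, mask, 0.1)
        hi = groupwise_objective([t, t], vols, tpl, mask, 10.0)
        assert hi > lo


class TestGroupwiseRegister:
    def test_identical_volumes_near_identity(self, phantom32):
        vols = [phantom32] * 4
        mask = sm.make_registration_mask(phantom32, "full")
        gw = sm.groupwise_register(vols, mask, levels=2, iters_per_level=60)
        for t in gw.transforms:
            trans, rot = sm.transform_distance(t, sm.IDENTITY)
            assert trans < 0.05 and rot < 0.05

    def test_known_transform_recovery(self, known_motion_volumes64):
        """Generator-as-oracle: recovers 2-voxel / 2-degree transforms
        within 0.2 voxel / 0.2 degree mean error after gauge removal."""
        gt, vols, mask = known_motion_volumes64
        gw = sm.groupwise_register(vols, mask, levels=3, iters_per_level=200,
                                   alternations=3)
        mm, deg = sm.trajectory_error(gw.trajectory(), gt)
        assert mm < 0.2
        assert deg < 0.2

    def test_strong_regularization_pins_identity(self, known_motion_volumes):
        gt, vols, mask = known_motion_volumes
        gw = sm.groupwise_register(vols[:4], mask, levels=2,
                                   iters_per_level=60, reg_weight=1e12)
        for t in gw.transforms:
            trans, rot = sm.transform_distance(t, sm.IDENTITY)
            assert trans < 0.05 and rot < 0.05

    def test_objective_trace_nonincreasing_within_level(self, known_motion_volumes):
        gt, vols, mask = known_motion_volumes
        gw = sm.groupwise_register(vols[:4], mask, levels=2,
                                   iters_per_level=80, alternations=3)
        assert not gw.diverged
        by_level = {}
        for rec in gw.objective_trace:
            by_level.setdefault((rec["repeat"], rec["level"]), []).append(
                rec["value"])
        for vals in by_level.values():
            assert all(vals[i + 1] <= vals[i] * 1.0001
                       for i in range(len(vals) - 1))

    def test_gauge_invariance(self, phantom32):
        """Pre-composing every true transform with a common g leaves the
        gauge-removed estimates unchanged."""
        gt = sm.sample_random_trajectory(4, 1.5, 1.5, seed=7, n_shots=4)
        g = sm.RigidTransform(t=(2, -1, 1), r=(3, 2, -2))
        mask = sm.make_registration_mask(phantom32, "full")
        vols_a = [sm.apply_rigid(phantom32, s) for s in gt.states]
        shifted = sm.MotionTrajectory([sm.compose(g, s) for s in gt.states],
                                      list(gt.assignment))
        vols_b = [sm.apply_rigid(phantom32, s) for s in shifted.states]
        gw_a = sm.groupwise_register(vols_a, mask, levels=2,
                                     iters_per_level=80)
        gw_b = sm.groupwise_register(vols_b, mask, levels=2,
                                     iters_per_level=80)
        mm_a, deg_a = sm.trajectory_error(gw_a.trajectory(), gt)
        mm_b, deg_b = sm.trajectory_error(gw_b.trajectory(), shifted)
        assert abs(mm_a - mm_b) < 0.15
        assert abs(deg_a - deg_b) < 0.15

    def test_mask_shields_outside_corruption(self, phantom32):
        """Corrupting voxels outside the registration mask barely moves the
        recovered transforms.

        The corruption is placed beyond the reach of the rigid warps and
        the pyramid smoothing (a few voxels outside the mask), since
        voxels immediately at the boundary legitimately enter the metric
        when anatomy moves across it.
        """
        from scipy.ndimage import binary_dilation
        gt = sm.sample_random_trajectory(4, 1.0, 1.0, seed=9, n_shots=4)
        vols = [sm.apply_rigid(phantom32, s) for s in gt.states]
        mask = sm.make_registration_mask(phantom32, "head_only")
        far = ~binary_dilation(mask, iterations=6)
        rng = np.random.default_rng(0)
        corrupted = []
        for v in vols:
            d = v.data.copy()
            sel = far & (rng.uniform(size=d.shape) < 0.1)
            d[sel] += rng.uniform(0, 1, int(sel.sum()))
            corrupted.append(sm.Volume(d, v.spacing))
        gw_clean = sm.groupwise_register(vols, mask, levels=2,
                                         iters_per_level=80)
        gw_corr = sm.groupwise_register(corrupted, mask, levels=2,
                                        iters_per_level=80)
        for a, b in zip(gw_clean.transforms, gw_corr.transforms):
            trans, rot = sm.transform_distance(a, b)
            assert trans < 0.05 and rot < 0.05

    def test_needs_two_volumes(self, phantom32):
        with pytest.raises(ValueError):
            sm.groupwise_register([phantom32], np.ones(phantom32.shape, bool))


class TestPairwise:
    def test_recovers_inverse_transform(self, phantom48):
        theta = sm.RigidTransform(t=(1.5, -0.8, 0.6), r=(2, -1.5, 1.0))
        moved = sm.apply_rigid(phantom48, theta)
        mask = sm.make_registration_mask(phantom48, "full")
        g = register_pairwise(moved, phantom48, mask, levels=3,
                              iters_per_level=200)
        trans, rot = sm.transform_distance(g, theta.invert())
        assert trans < 0.2 and rot < 0.3

    def test_cross_check_against_simpleitk(self, phantom48):
        """Independent toolbox cross-check: our pairwise rigid estimate
        agrees with SimpleITK's Euler3D registration to half a voxel."""
        sitk = pytest.importorskip("SimpleITK")
        theta = sm.RigidTransform(t=(2.0, -1.0, 0.5), r=(1.5, -1.0, 2.0))
        moved = sm.apply_rigid(phantom48, theta)
        mask = sm.make_registration_mask(phantom48, "full")
        ours = register_pairwise(moved, phantom48, mask, levels=3,
                                 iters_per_level=200)

        fixed = sitk.GetImageFromArray(phantom48.data.astype(np.float32))
        moving = sitk.GetImageFromArray(moved.data.astype(np.float32))
        reg = sitk.ImageRegistrationMethod()
        reg.SetMetricAsMeanSquares()
        reg.SetOptimizerAsRegularStepGradientDescent(
            learningRate=1.0, minStep=1e-4, numberOfIterations=300)
        reg.SetOptimizerScalesFromPhysicalShift()
        init = sitk.CenteredTransformInitializer(
            fixed, moving, sitk.Euler3DTransform(),
            sitk.CenteredTransformInitializerFilter.GEOMETRY)
        reg.SetInitialTransform(init, inPlace=False)
        reg.SetInterpolator(sitk.sitkLinear)
        out = reg.Execute(fixed, moving)
        # compare predicted displacement of a probe point; SimpleITK's
        # result maps fixed to moving space (the resampling direction),
        # i.e. the inverse of our alignment transform, and its array
        # indexing is (z, y, x)
        probe = np.array([30.0, 25.0, 20.0])
        ours_disp = ours.matrix() @ (probe - 23.5) + 23.5 \
            + np.asarray(ours.t) - probe
        p_sitk = np.array(out.TransformPoint(tuple(probe[::-1])))[::-1]
        sitk_disp = p_sitk - probe
        assert np.linalg.norm(ours_disp + sitk_disp) < 0.5
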