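"""Rigid-transform group algebra, motion statistics, gauge removal."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import segmoco as sm
from segmoco.motion import mean_transform

from conftest import random_transform


angles = st.floats(-170, 170, allow_nan=False)
shifts = st.floats(-20, 20, allow_nan=False)
transform_st = st.builds(
    lambda tx, ty, tz, rx, ry, rz: sm.RigidTransform((tx, ty, tz), (rx, ry, rz)),
    shifts, shifts, shifts, angles, angles, angles)


class TestGroupAlgebra:
    def test_identity_law(self, rng):
        t = random_transform(rng)
        assert np.allclose(sm.compose(sm.IDENTITY, t).params, t.params)
        assert np.allclose(sm.compose(t, sm.IDENTITY).params, t.params)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(transform_st)
    def test_inverse_law(self, t):
        ident = sm.compose(t, sm.invert(t))
        assert np.abs(ident.params).max() < 1e-10

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(transform_st, transform_st, transform_st)
    def test_associativity(self, a, b, c):
        left = sm.compose(sm.compose(a, b), c)
        right = sm.compose(a, sm.compose(b, c))
        assert np.allclose(left.matrix(), right.matrix(), atol=1e-10)
        assert np.allclose(left.t, right.t, atol=1e-9)

    def test_compose_matches_matrix_product(self, rng):
        """Rotation of a composition equals the 3x3 matrix product."""
        for _ in range(10):
            a, b = random_transform(rng, rot=40), random_transform(rng, rot=40)
            assert np.allclose(sm.compose(a, b).matrix(),
                               a.matrix() @ b.matrix(), atol=1e-12)

    def test_angles_canonicalized(self):
        t = sm.RigidTransform(r=(190.0, -270.0, 360.0))
        assert t.r == (-170.0, 90.0, 0.0)


class TestTransformDistance:
    def test_self_distance_zero(self, rng):
        t = random_transform(rng)
        assert sm.transform_distance(t, t) == pytest.approx((0.0, 0.0),
                                                            abs=1e-10)

    def test_pure_translation(self):
        a = sm.RigidTransform(t=(2.0, 0.0, 0.0))
        assert sm.transform_distance(a, sm.IDENTITY) == (2.0, 0.0)

    def test_rotation_angle_matches_trace_formula(self, rng):
        """Geodesic angle equals arccos((trace(R_rel) - 1) / 2)."""
        for _ in range(10):
            a, b = random_transform(rng, rot=30), random_transform(rng, rot=30)
            _, rot = sm.transform_distance(a, b)
            rrel = b.matrix().T @ a.matrix()
            expected = np.degrees(np.arccos(np.clip((np.trace(rrel) - 1) / 2,
                                                    -1, 1)))
            assert rot == pytest.approx(expected, abs=1e-8)

    def test_symmetry_and_triangle_inequality(self, rng):
        for _ in range(20):
            a, b, c = (random_transform(rng, rot=30) for _ in range(3))
            dab = sm.transform_distance(a, b)
            dba = sm.transform_distance(b, a)
            assert dab == pytest.approx(dba, abs=1e-9)
            dac = sm.transform_distance(a, c)
            dcb = sm.transform_distance(c, b)
            assert dab[1] <= dac[1] + dcb[1] + 1e-9


class TestRandomTrajectory:
    def test_degenerate_stds_give_identity(self):
        traj = sm.sample_random_trajectory(5, 0.0, 0.0, seed=0)
        assert all(s.is_identity() for s in traj.states)

    def test_determinism(self):
        a = sm.sample_random_trajectory(16, 2, 1, seed=7)
        b = sm.sample_random_trajectory(16, 2, 1, seed=7)
        assert all(x.params.tolist() == y.params.tolist()
                   for x, y in zip(a.states, b.states))

    @pytest.mark.parametrize("trans_std,rot_std,expected", [
        (2.0, 1.0, 4.5), (12.0, 6.0, 27.1)])
    def test_mean_center_distance_statistic(self, trans_std, rot_std, expected):
        """Mean pairwise distance between transformed volume centers matches
        the closed form 4*sigma/sqrt(pi) for i.i.d. N(0, sigma^2) motion."""
        got = sm.monte_carlo_center_distance(trans_std, rot_std,
                                             n_pairs=100_000, seed=11)
        assert got == pytest.approx(expected, abs=0.1)

    def test_monte_carlo_standard_error(self):
        """Standard error < 0.05 mm at 1e5 pair draws (convergence)."""
        vals = [sm.monte_carlo_center_distance(2, 1, 100_000, seed=s)
                for s in range(5)]
        assert np.std(vals) < 0.05


class TestIntrasegmentMotion:
    def test_zero_severity_repeats_states(self):
        base = sm.sample_random_trajectory(4, 2, 1, seed=0, n_shots=20)
        fine = sm.add_intrasegment_motion(base, 20, 0.0, seed=1)
        for i, s in enumerate(fine.states):
            assert np.allclose(s.params, base.states[i // 5].params)

    def test_perturbation_severity(self):
        """64 -> 320 states at 1/16 severity gives perturbation stds of
        0.125 mm and 0.0625 deg on the added components."""
        base = sm.sample_random_trajectory(64, 2.0, 1.0, seed=2, n_shots=320)
        fine = sm.add_intrasegment_motion(base, 320, 1.0 / 16.0, seed=3,
                                          trans_std_mm=2.0, rot_std_deg=1.0)
        # recover the added perturbations: pert = fine ∘ base^-1
        dt, dr = [], []
        for i, s in enumerate(fine.states):
            pert = sm.compose(s, sm.invert(base.states[i // 5]))
            dt.extend(pert.t)
            dr.extend(pert.r)
        assert np.std(dt) == pytest.approx(2.0 / 16.0, rel=0.15)
        assert np.std(dr) == pytest.approx(1.0 / 16.0, rel=0.15)

    def test_determinism(self):
        base = sm.sample_random_trajectory(4, 2, 1, seed=0, n_shots=8)
        a = sm.add_intrasegment_motion(base, 8, 0.5, seed=9)
        b = sm.add_intrasegment_motion(base, 8, 0.5, seed=9)
        assert all(x.params.tolist() == y.params.tolist()
                   for x, y in zip(a.states, b.states))

    def test_incompatible_counts(self):
        base = sm.sample_random_trajectory(4, 2, 1, seed=0)
        with pytest.raises(ValueError):
            sm.add_intrasegment_motion(base, 10, 0.5, seed=0)


class TestScriptedTrajectories:
    def test_stepwise_zero_amplitude_is_identity(self):
        traj = sm.make_scripted_trajectory("stepwise_extreme", 8,
                                           amplitude_mm=0, amplitude_deg=0)
        assert all(s.is_identity(tol=1e-12) for s in traj.states)

    def test_stepwise_endpoints_and_monotonicity(self):
        traj = sm.make_scripted_trajectory("stepwise_extreme", 64,
                                           amplitude_deg=10.0, seed=4)
        r = np.array([s.r for s in traj.states])
        assert np.linalg.norm(r[0]) == pytest.approx(10.0, abs=1e-9)
        assert np.linalg.norm(r[-1]) == pytest.approx(10.0, abs=1e-9)
        assert np.allclose(r[0], -r[-1], atol=1e-9)
        # monotone progression along the motion axis
        proj = r @ (r[-1] / np.linalg.norm(r[-1]))
        assert np.all(np.diff(proj) > 0)

    def test_jittery_distinct_state_count(self):
        traj = sm.make_scripted_trajectory("jittery", 20, amplitude_deg=5,
                                           jump_period=6, seed=1)
        distinct = {s.params.tobytes() for s in traj.states}
        assert len(distinct) == int(np.ceil(20 / 6))

    def test_unknown_pattern(self):
        with pytest.raises(ValueError):
            sm.make_scripted_trajectory("wobble", 8)


class TestGaugeRemoval:
    def test_identical_trajectories_unchanged(self):
        gt = sm.sample_random_trajectory(8, 2, 1, seed=5)
        out = sm.remove_global_offset(gt, gt)
        mm = np.mean([sm.transform_distance(a, b)[0]
                      for a, b in zip(out.states, gt.states)])
        assert mm < 1e-8

    def test_pure_gauge_removed(self):
        gt = sm.sample_random_trajectory(8, 2, 1, seed=5)
        g = sm.RigidTransform(t=(3, -1, 2), r=(4, -6, 2))
        est = sm.MotionTrajectory([sm.compose(g, s) for s in gt.states],
                                  list(gt.assignment))
        out = sm.remove_global_offset(est, gt)
        d = [sm.transform_distance(a, b) for a, b in zip(out.states, gt.states)]
        assert np.max(d) < 1e-6

    def test_beats_coarse_grid_search(self, rng):
        """The polished gauge is at least as good as a brute-force search
        over a coarse 6-D grid of candidate offsets."""
        gt = sm.sample_random_trajectory(6, 2, 1, seed=6)
        est = sm.MotionTrajectory(
            [random_transform(rng, trans=2, rot=2) for _ in range(6)],
            list(gt.assignment))
        out = sm.remove_global_offset(est, gt)

        def mean_sq(traj):
            d = [sm.transform_distance(a, b)
                 for a, b in zip(traj.states, gt.states)]
            return np.mean([x ** 2 + y ** 2 for x, y in d])

        ours = mean_sq(out)
        grid = np.linspace(-2, 2, 5)
        best = np.inf
        for tx in grid:
            for ry in grid:
                g = sm.RigidTransform(t=(tx, 0, 0), r=(0, ry, 0))
                cand = sm.MotionTrajectory(
                    [sm.compose(g, s) for s in est.states],
                    list(est.assignment))
                best = min(best, mean_sq(cand))
        assert ours <= best + 1e-9

    def test_never_increases_mean_distance(self, rng):
        gt = sm.sample_random_trajectory(8, 2, 1, seed=8)
        est = sm.MotionTrajectory(
            [random_transform(rng, trans=3, rot=4) for _ in range(8)],
            list(gt.assignment))
        before = np.mean([sm.transform_distance(a, b)[0] ** 2
                          + sm.transform_distance(a, b)[1] ** 2
                          for a, b in zip(est.states, gt.states)])
        out = sm.remove_global_offset(est, gt)
        after = np.mean([sm.transform_distance(a, b)[0] ** 2
                         + sm.transform_distance(a, b)[1] ** 2
                         for a, b in zip(out.states, gt.states)])
        assert after <= before + 1e-9


class TestTrajectoryContainer:
    def test_noncontiguous_assignment_rejected(self):
        with pytest.raises(ValueError):
            sm.MotionTrajectory([sm.IDENTITY, sm.IDENTITY], [0, 1, 0])

    def test_json_round_trip(self):
        traj = sm.sample_random_trajectory(4, 2, 1, seed=0, n_shots=8)
        back = sm.MotionTrajectory.from_dict(traj.to_dict())
        assert all(np.allclose(a.params, b.params)
                   for a, b in zip(traj.states, back.states))
        assert back.assignment == traj.assignment

    def test_resample_to_coarser_grid(self):
        fine = sm.sample_random_trajectory(8, 2, 1, seed=0, n_shots=8)
        coarse_ref = sm.MotionTrajectory.identity(4, 8)
        res = fine.resample_to(coarse_ref)
        assert res.n_states == 4
        # each coarse state equals the fine state of its first shot
        assert np.allclose(res.states[1].params, fine.states[2].params)


def test_mean_transform_of_identical_inputs():
    t = sm.RigidTransform(t=(1, 2, 3), r=(10, 20, 30))
    m = mean_transform([t, t, t])
    assert np.allclose(m.params, t.params, atol=1e-9)
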