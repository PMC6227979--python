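import math

import numpy as np
import pytest

import jumpstab as js
from jumpstab.kinematics import JOINT_NAMES


@pytest.fixture()
def morph():
    return js.MorphologyParams(body_mass=1.42, body_inertia=4.3e-3, l_foot=0.06,
                               l_tmt=0.08, l_tibiotarsus=0.12, l_femur=0.07)


def independent_chain(morph, q, foot_pose):
    """Hand-rolled forward kinematics via complex rotations (test oracle)."""
    q_hip, q_knee, q_ankle, q_tmt = q
    x_f, y_f, phi_f = foot_pose
    pos = complex(x_f, y_f)
    ang = phi_f + q_tmt
    points = []
    for l, dq in [(morph.l_tmt, 0.0), (morph.l_tibiotarsus, math.pi + q_ankle),
                  (morph.l_femur, math.pi + q_knee)]:
        ang += dq
        pos += l * complex(math.cos(ang), math.sin(ang))
        points.append(pos)
    phi_B = ang + math.pi + q_hip
    ox, oy = morph.hip_offset
    cog = pos + complex(ox, oy) * complex(math.cos(phi_B), math.sin(phi_B))
    return points, cog, phi_B


class TestForwardKinematics:
    def test_straight_vertical_leg(self, morph):
        q = [math.pi / 2, math.pi, math.pi, math.pi / 2]
        st = js.forward_kinematics(morph, q, (0.0, 0.0, 0.0))
        total = morph.l_tmt + morph.l_tibiotarsus + morph.l_femur
        assert st.cog == pytest.approx((0.0, total), abs=1e-12)
        assert st.phi_B % (2 * math.pi) == pytest.approx(0.0, abs=1e-12)
        assert st.front_toe == pytest.approx((morph.l_foot, 0.0), abs=1e-12)

    def test_rotating_foot_pose_rotates_all_points(self, morph):
        rng = np.random.default_rng(7)
        q = rng.uniform(0.3, 5.0, size=4)
        delta = 0.37
        st0 = js.forward_kinematics(morph, q, (0.2, 0.1, 0.4))
        st1 = js.forward_kinematics(morph, q, (0.2, 0.1, 0.4 + delta))
        rot = complex(math.cos(delta), math.sin(delta))
        pivot = complex(0.2, 0.1)
        for name, p0 in st0.joint_positions.items():
            p1 = st1.joint_positions[name]
            expected = pivot + (complex(*p0) - pivot) * rot
            assert p1 == pytest.approx((expected.real, expected.imag), abs=1e-12), name

    def test_matches_independent_chain(self, morph):
        rng = np.random.default_rng(11)
        morph2 = js.MorphologyParams(body_mass=1.42, body_inertia=4.3e-3, l_foot=0.06,
                                     l_tmt=0.08, l_tibiotarsus=0.12, l_femur=0.07,
                                     hip_offset=(0.01, -0.02))
        for _ in range(10):
            q = rng.uniform(-1.0, 6.0, size=4)
            pose = rng.uniform(-0.5, 0.5, size=3)
            st = js.forward_kinematics(morph2, q, pose)
            pts, cog, phi_B = independent_chain(morph2, q, pose)
            assert st.hip == pytest.approx((pts[-1].real, pts[-1].imag), abs=1e-12)
            assert st.cog == pytest.approx((cog.real, cog.imag), abs=1e-12)
            assert math.remainder(st.phi_B - phi_B, 2 * math.pi) == pytest.approx(0, abs=1e-12)

    def test_chain_closure(self, morph):
        rng = np.random.default_rng(3)
        for _ in range(20):
            q = rng.uniform(-2.0, 6.0, size=4)
            st = js.forward_kinematics(morph, q, rng.uniform(-1, 1, size=3))
            for a, b, l in [(st.rear_toe, st.ankle, morph.l_tmt),
                            (st.ankle, st.knee, morph.l_tibiotarsus),
                            (st.knee, st.hip, morph.l_femur),
                            (st.rear_toe, st.front_toe, morph.l_foot)]:
                assert math.dist(a, b) == pytest.approx(l, abs=1e-12)


class TestJointTrajectorySet:
    def test_reproduces_knots_exactly(self, gf_fixture):
        traj = gf_fixture.traj
        at_knots = traj.angles(traj.knot_times)
        assert np.max(np.abs(at_knots - traj.knot_angles)) < 1e-12

    def test_derivatives_match_finite_differences(self, gf_fixture):
        traj = gf_fixture.traj
        t0, t1 = traj.domain
        rng = np.random.default_rng(5)
        h = 1e-6
        for t in rng.uniform(t0 + 0.01, t1 - 0.01, size=8):
            qm, q0, qp = traj.angles(t - h), traj.angles(t), traj.angles(t + h)
            rate_fd = (qp - qm) / (2 * h)
            acc_fd = (qp - 2 * q0 + qm) / h**2
            rate = traj.rates(t)
            acc = traj.accelerations(t)
            assert rate == pytest.approx(rate_fd, rel=1e-4, abs=1e-6)
            assert acc == pytest.approx(acc_fd, rel=1e-3, abs=1e-2)

    def test_scalar_fast_path_matches_vectorised(self, gf_fixture):
        traj = gf_fixture.traj
        t0, t1 = traj.domain
        for t in np.linspace(t0, t1, 17):
            q, qd, qdd = traj.eval_scalar(float(t))
            assert q == pytest.approx(traj.angles(t), abs=1e-13)
            assert qd == pytest.approx(traj.rates(t), abs=1e-11)
            assert qdd == pytest.approx(traj.accelerations(t), abs=1e-9)

    def test_too_few_knots_rejected(self):
        with pytest.raises(ValueError, match="4 knots"):
            js.JointTrajectorySet([0.0, 0.1, 0.2], np.zeros((3, 4)))

    def test_out_of_domain_rejected(self, gf_fixture):
        with pytest.raises(ValueError, match="domain"):
            gf_fixture.traj.angles(gf_fixture.traj.domain[1] + 0.5)


class TestChainDerivatives:
    def test_frozen_joints_translation(self, morph):
        times = np.linspace(0, 1, 5)
        traj = js.JointTrajectorySet(times, np.tile([1.2, 2.8, 2.5, 1.8], (5, 1)))
        v = (0.3, -0.2, 0.0)
        kin = js.chain_derivatives(morph, traj, (0, 0, 0), v, 0.5)
        assert kin.velocity == pytest.approx(v[:2], abs=1e-12)
        assert kin.omega == pytest.approx(0.0, abs=1e-12)

    def test_frozen_joints_spin_about_rear_toe(self, morph):
        times = np.linspace(0, 1, 5)
        traj = js.JointTrajectorySet(times, np.tile([1.2, 2.8, 2.5, 1.8], (5, 1)))
        omega = 2.0
        kin = js.chain_derivatives(morph, traj, (0, 0, 0), (0, 0, omega), 0.5)
        r = math.dist(kin.state.cog, kin.state.rear_toe)
        assert math.hypot(*kin.velocity) == pytest.approx(omega * r, rel=1e-12)
        assert kin.omega == pytest.approx(omega)

    def test_acceleration_matches_finite_differences(self, gf_fixture):
        """Analytic chain acceleration vs central differences of the FK positions."""
        morph, traj = gf_fixture.morph, gf_fixture.traj
        rng = np.random.default_rng(13)
        h = 1e-5
        pose, rates = (0.0, 0.0, 0.05), (0.0, 0.0, 0.0)
        for t in rng.uniform(0.31, 0.43, size=5):
            def cog_at(tv):
                st = js.forward_kinematics(morph, traj.angles(tv), pose)
                return np.array(st.cog)

            acc_fd = (cog_at(t - h) - 2 * cog_at(t) + cog_at(t + h)) / h**2
            kin = js.chain_derivatives(morph, traj, pose, rates, t)
            assert kin.acceleration == pytest.approx(acc_fd, rel=1e-4, abs=1e-4)

    def test_jacobian_is_rigid_body_map(self, gf_fixture):
        morph, traj = gf_fixture.morph, gf_fixture.traj
        kin = js.chain_derivatives(morph, traj, (0.1, 0.02, 0.3), (0, 0, 0), 0.2)
        x_B, y_B = kin.state.cog
        expected = np.array([[1, 0, -(y_B - 0.02)], [0, 1, x_B - 0.1], [0, 0, 1]])
        assert kin.jacobian == pytest.approx(expected)

    def test_out_of_domain(self, gf_fixture):
        with pytest.raises(ValueError, match="domain"):
            js.chain_derivatives(gf_fixture.morph, gf_fixture.traj, (0, 0, 0), (0, 0, 0), 99.0)


class TestPerturbTrajectory:
    def test_identity_scale(self, gf_fixture):
        traj = gf_fixture.traj
        out = js.perturb_trajectory(traj, "tmt", 1.0, (0.30, 0.44))
        tt = np.linspace(*traj.domain, 301)
        assert np.max(np.abs(out.angles(tt) - traj.angles(tt))) < 1e-12

    def test_zero_scale_freezes_joint_in_window_core(self, gf_fixture):
        traj = gf_fixture.traj
        out = js.perturb_trajectory(traj, "tmt", 0.0, (0.30, 0.44))
        core = np.linspace(0.32, 0.42, 50)  # inside the blend margins
        j = JOINT_NAMES.index("tmt")
        # rates are O(1) rad/s unperturbed; the frozen joint's residual rate is
        # only spline-reinterpolation error
        assert np.max(np.abs(out.rates(core)[:, j])) < 5e-4
        # other joints untouched
        others = [i for i in range(4) if i != j]
        tt = np.linspace(*traj.domain, 200)
        assert np.max(np.abs(out.angles(tt)[:, others] - traj.angles(tt)[:, others])) < 1e-12

    def test_angle_unchanged_before_window(self, gf_fixture):
        traj = gf_fixture.traj
        out = js.perturb_trajectory(traj, "knee", 1.5, (0.30, 0.44))
        tt = np.linspace(0.0, 0.299, 100)
        # knot values are untouched before the window; the natural spline's
        # global coupling leaks a little curvature across the window edge
        assert np.max(np.abs(out.angles(tt) - traj.angles(tt))) < 1e-8

    def test_faster_tmt_extension_delays_toe_off(self, gf_fixture):
        """A faster TMT extension sustains the leg acceleration and delays toe-off."""
        cfg = js.SimConfig(dt=1e-4)
        base = js.simulate_ground(gf_fixture.morph, gf_fixture.traj, cfg)
        t_base = js.final_toe_off_time(base)
        fast = js.perturb_trajectory(gf_fixture.traj, "tmt", 1.2, (0.30, 0.46))
        pert = js.simulate_ground(gf_fixture.morph, fast, cfg)
        t_pert = js.final_toe_off_time(pert)
        assert t_pert > t_base

    def test_bad_window_rejected(self, gf_fixture):
        with pytest.raises(ValueError, match="window"):
            js.perturb_trajectory(gf_fixture.traj, "tmt", 1.2, (0.4, 9.0))
        with pytest.raises(ValueError, match="joint"):
            js.perturb_trajectory(gf_fixture.traj, "toe", 1.2, (0.3, 0.4))
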