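"""Ground-model integration, perch inverse dynamics and wing loads."""

import math
from dataclasses import replace

import numpy as np
import pytest

import jumpstab as js
from jumpstab.dynamics import wing_inertial_loads

G = 9.81


def frozen_trajectory(q, t_end=0.4):
    times = np.linspace(0.0, t_end, 9)
    return js.JointTrajectorySet(times, np.tile(q, (9, 1)))


@pytest.fixture()
def morph():
    return js.MorphologyParams(body_mass=1.42, body_inertia=4.3e-3, l_foot=0.06,
                               l_tmt=0.08, l_tibiotarsus=0.12, l_femur=0.07)


class TestGroundStatics:
    def test_settles_under_body_weight(self, morph):
        # stable standing pose, frozen joints: total normal force -> m g,
        # CoP under the CoG
        q = np.deg2rad(js.Pose(102.0, 44.0, 125.0, 5.0).joint_angles_deg())
        traj = frozen_trajectory(q)
        res = js.simulate_ground(morph, traj, js.SimConfig(dt=5e-5))
        late = res.t > 0.3
        total = res.RAy[late] + res.RCy[late]
        assert np.max(np.abs(total - morph.weight)) / morph.weight < 1e-3
        assert np.nanmax(np.abs(res.x_P[late] - res.x_B[late])) < 1e-4

    def test_tipping_matches_pendulum_oracle(self, morph):
        """Frozen joints with the CoG ahead of the front toe: the system falls
        over the front node like a rigid pendulum."""
        # lean the whole leg far forward so the CoG passes the front toe
        q = np.deg2rad(js.Pose(70.0, 30.0, 100.0, 5.0).joint_angles_deg())
        traj = frozen_trajectory(q, t_end=0.25)
        st0 = js.forward_kinematics(morph, q, (0.0, 0.0, 0.0))
        assert st0.cog[0] > morph.l_foot  # CoG ahead of the front toe
        res = js.simulate_ground(morph, traj, js.SimConfig(dt=2e-5))

        # oracle: rigid-body pendulum about the front toe
        from scipy.integrate import solve_ivp

        pivot = np.array(st0.front_toe)
        r = np.array(st0.cog) - pivot
        dist = np.hypot(*r)
        I_p = morph.body_inertia + morph.body_mass * dist**2
        psi0 = math.atan2(r[1], r[0])

        def rhs(t, s):
            psi, om = s
            return [om, -morph.body_mass * G * dist * math.cos(psi) / I_p]

        t_eval = res.t[res.t <= 0.25]
        sol = solve_ivp(rhs, (0, t_eval[-1]), [psi0, 0.0], t_eval=t_eval, rtol=1e-10)
        rotation_oracle = sol.y[0] - psi0
        # compare the accumulated foot rotation while still on the ground
        mask = (t_eval > 0.05) & (np.abs(rotation_oracle) < 0.5)
        sim_rot = res.phi_f[: len(t_eval)][mask]
        orc_rot = rotation_oracle[mask]
        err = np.max(np.abs(sim_rot - orc_rot)) / np.max(np.abs(orc_rot))
        assert err < 0.1


class TestBallisticsAndImpulse:
    def test_ballistic_parabola_after_toe_off(self, firm_run):
        t_off = js.final_toe_off_time(firm_run)
        air = firm_run.t > t_off + 5e-3
        t = firm_run.t[air]
        y = firm_run.y_B[air]
        coeffs = np.polyfit(t, y, 2)
        resid = y - np.polyval(coeffs, t)
        assert coeffs[0] == pytest.approx(-G / 2, rel=1e-6)
        assert np.max(np.abs(resid)) < 1e-9

    def test_pitch_rate_constant_in_flight(self, firm_run):
        # buffer past toe-off: sub-tolerance contact forces persist briefly
        # while the unilateral springs finish unloading
        t_off = js.final_toe_off_time(firm_run)
        air = firm_run.t > t_off + 1e-2
        om = firm_run.omega_B[air]
        assert np.ptp(om) < 1e-9

    def test_impulse_equals_momentum_change(self, firm_run):
        m = firm_run.morph.body_mass
        t = firm_run.t
        jx = np.trapezoid(firm_run.RPx, t) / m
        jy = np.trapezoid(firm_run.RPy, t) / m - G * (t[-1] - t[0])
        dvx = firm_run.vx_B[-1] - firm_run.vx_B[0]
        dvy = firm_run.vy_B[-1] - firm_run.vy_B[0]
        scale = math.hypot(firm_run.vx_B[-1], firm_run.vy_B[-1])
        assert abs(jx - dvx) / scale < 1e-3
        assert abs(jy - dvy) / scale < 1e-3

    def test_normal_forces_unilateral(self, firm_run, soft_run):
        for run in (firm_run, soft_run):
            assert run.RAy.min() >= 0.0
            assert run.RCy.min() >= 0.0

    def test_cop_between_nodes_under_double_contact(self, firm_run):
        both = (firm_run.RAy > 0) & (firm_run.RCy > 0)
        x_p = firm_run.x_P[both]
        assert np.all(x_p >= firm_run.x_f[both] - 1e-12)
        assert np.all(x_p <= firm_run.front_toe_x[both] + 1e-12)


class TestReducedVsPenaltyFormulation:
    def test_matches_brute_force_penalty_model(self, gf_fixture):
        """The 3-DoF reduced model must agree with a brute-force formulation:
        the body as a free rigid body tied to a (near-massless) foot by very
        stiff joint-following penalty springs (0.02 s segment)."""
        from helpers import penalty_formulation_error

        assert penalty_formulation_error(gf_fixture) < 0.01


class TestPerchInverseDynamics:
    def test_static_pose_reactions(self, morph):
        q = np.deg2rad([63.0, -103.0, -237.0, 102.0])
        traj = frozen_trajectory(q)
        res = js.simulate_perch(morph, traj, js.SimConfig(output_dt=1e-3))
        st = js.forward_kinematics(morph, q, (0.0, 0.0, 0.0))
        assert np.allclose(res.RPx, 0.0, atol=1e-9)
        assert np.allclose(res.RPy, morph.weight, atol=1e-9)
        expected_torque = morph.weight * st.cog[0]
        assert np.allclose(res.T_grip, expected_torque, atol=1e-9)

    def test_newton_euler_residuals(self, dove_fixture, dove_perch_run):
        """R_P and T_grip must exactly balance the body's rates of change of
        linear and angular momentum at every sample."""
        m = dove_fixture.morph.body_mass
        I_B = dove_fixture.morph.body_inertia
        r = dove_perch_run
        x_p, y_p = r.meta["perch_point"]
        res_fx = r.RPx - m * r.ax_B
        res_fy = r.RPy - m * (r.ay_B + G)
        res_t = (r.T_grip + (x_p - r.x_B) * r.RPy - (y_p - r.y_B) * r.RPx
                 - I_B * r.alpha_B)
        assert np.max(np.abs(res_fx)) < 1e-9
        assert np.max(np.abs(res_fy)) < 1e-9
        assert np.max(np.abs(res_t)) < 1e-9

    def test_mass_scaling_leaves_normalised_reactions_unchanged(self, dove_fixture):
        """Doubling body mass at fixed geometry and kinematics (inertia scales
        with mass for a fixed-shape body) leaves F/(m g) and T/(m g L_max)
        histories unchanged."""
        morph = dove_fixture.morph
        cfg = js.SimConfig(output_dt=1e-3)
        r1 = js.simulate_perch(morph, dove_fixture.traj, cfg)
        morph2 = replace(morph, body_mass=2 * morph.body_mass,
                         body_inertia=2 * morph.body_inertia)
        r2 = js.simulate_perch(morph2, dove_fixture.traj, cfg)
        n1 = js.normalize(r1, morph)
        n2 = js.normalize(r2, morph2)
        for col in ("Fx_norm", "Fy_norm", "T_grip_norm"):
            a, b = n1[col].to_numpy(), n2[col].to_numpy()
            assert np.max(np.abs(a - b)) / max(1.0, np.max(np.abs(a))) < 1e-9

    def test_geometric_upscaling_increases_normalised_loads(self, dove_fixture):
        """Geometric scale-up at fixed joint kinematics raises normalized
        reaction force and torque (accelerations scale with length)."""
        morph = dove_fixture.morph
        cfg = js.SimConfig(output_dt=1e-3)
        r1 = js.simulate_perch(morph, dove_fixture.traj, cfg)
        s = 2.0
        morph2 = replace(
            morph,
            body_mass=morph.body_mass * s**3,
            body_inertia=morph.body_inertia * s**5,
            l_foot=morph.l_foot * s, l_tmt=morph.l_tmt * s,
            l_tibiotarsus=morph.l_tibiotarsus * s, l_femur=morph.l_femur * s,
        )
        r2 = js.simulate_perch(morph2, dove_fixture.traj, cfg)
        s1 = js.takeoff_summary(r1, morph)
        s2 = js.takeoff_summary(r2, morph2)
        assert s2.peak_force_norm > s1.peak_force_norm
        assert s2.peak_grip_torque_norm > s1.peak_grip_torque_norm


class TestWingInertialLoads:
    def test_massless_wing(self):
        w = js.WingParams(wing_total_mass=0.0)
        assert wing_inertial_loads(w, 0.05) == (0.0, 0.0, 0.0)

    def test_frozen_pose_gives_static_weight_and_moment(self):
        w = js.WingParams(wing_total_mass=0.009, upstroke_period=0.08)
        fx, fy, tq = wing_inertial_loads(w, 1.0)  # long after the upstroke
        assert fx == pytest.approx(0.0, abs=1e-12)
        assert fy == pytest.approx(-0.009 * G, rel=1e-12)
        # static moment of the three point masses about the shoulder
        e = min(1.0, w.initial_extension + w.extension_amplitude)
        eta = w.initial_elevation + w.elevation_amplitude
        l1, l2, l3 = w.segment_lengths
        xs = [e * c * math.cos(eta) for c in (l1 / 2, l1 + l2 / 2, l1 + l2 + l3 / 2)]
        assert tq == pytest.approx(-sum(0.003 * G * x for x in xs), rel=1e-12)

    def test_force_matches_finite_differences_of_wing_com(self):
        """Net wing force = -(total mass) x (CoM acceleration) - weight,
        checked against numerical differentiation of the mass positions."""
        w = js.WingParams(wing_total_mass=0.009, upstroke_period=0.08,
                          start_time=0.01)

        def positions(t):
            u = (t - w.start_time) / w.upstroke_period
            u = min(1.0, max(0.0, u))
            s = u**3 * (10 + u * (-15 + 6 * u))
            eta = w.initial_elevation + w.elevation_amplitude * s
            e = min(1.0, w.initial_extension + w.extension_amplitude * s)
            l1, l2, l3 = w.segment_lengths
            return np.array([[e * c * math.cos(eta), e * c * math.sin(eta)]
                             for c in (l1 / 2, l1 + l2 / 2, l1 + l2 + l3 / 2)])

        h = 1e-6
        for t in (0.02, 0.04, 0.06, 0.08):
            acc = (positions(t + h) - 2 * positions(t) + positions(t - h)) / h**2
            fx_fd = -0.003 * acc[:, 0].sum()
            fy_fd = -0.003 * acc[:, 1].sum() - 0.009 * G
            fx, fy, _ = wing_inertial_loads(w, t)
            assert fx == pytest.approx(fx_fd, rel=1e-4, abs=1e-6)
            assert fy == pytest.approx(fy_fd, rel=1e-4, abs=1e-6)

    def test_upstroke_peak_reaction_exceeds_static_weight(self):
        # while the wing accelerates upward the body must push it up, so the
        # reaction on the body exceeds the static wing weight at some phase
        w = js.WingParams(wing_total_mass=0.009, upstroke_period=0.08,
                          initial_elevation=math.radians(-60.0))
        fy_min = min(wing_inertial_loads(w, t)[1] for t in np.linspace(0.0, 0.08, 200))
        assert fy_min < -0.009 * G


class TestIntegrationGuards:
    def test_instability_raises_with_guidance(self, dove_fixture):
        # a dove-scale *ground* model at the nominal step is outside the
        # explicit scheme's stability limit (tiny pitch inertia vs the
        # tangential damper) and must fail loudly, not return garbage
        with pytest.raises(js.IntegrationError, match="dt"):
            js.simulate_ground(dove_fixture.morph, dove_fixture.traj,
                               js.SimConfig(dt=2e-5))
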