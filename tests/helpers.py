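"""Independent oracles shared between test modules."""

import math

import numpy as np

import jumpstab as js

G = 9.81


def penalty_formulation_error(fixture, t_seg=0.02, dt=5e-7):
    """Body-position discrepancy between the reduced 3-DoF ground model and a
    brute-force penalty formulation, as a fraction of L_max.

    The brute force simulates the body as a free rigid body and the foot as a
    separate (near-massless) body carrying the contact forces, coupled by
    very stiff joint-following penalty springs that enforce the prescribed
    chain map between foot pose and body pose.
    """
    morph, traj = fixture.morph, fixture.traj
    m, I_B = morph.body_mass, morph.body_inertia
    cfg = js.SimConfig(dt=1e-6, output_dt=1e-4, t_span=(0.0, t_seg))
    ref = js.simulate_ground(morph, traj, cfg)

    params = cfg.contact
    k, c_n = params.stiffness, params.normal_damping(m)
    c_t = params.tangential_damping
    lf = morph.l_foot
    m_f = 1e-3 * m
    # foot inertia must absorb the penalty damper acting through the long
    # body lever (stability of the explicit oracle); still ~0.5% of I_B
    I_f = 2e-5
    K, C = 1e7, 4.0 * math.sqrt(1e7 * m_f)
    Kp, Cp = 1e3, 4.0 * math.sqrt(1e3 * I_f)

    # tabulate the prescribed chain map on the half-step grid
    ts_fine = np.arange(0.0, t_seg + 2 * dt, dt / 2)
    Q = traj.angles(np.minimum(ts_fine, traj.domain[1]))
    v0_tab = np.empty((len(ts_fine), 2))
    sigma_tab = np.empty(len(ts_fine))
    for i, q in enumerate(Q):
        st = js.forward_kinematics(morph, q, (0.0, 0.0, 0.0))
        v0_tab[i] = st.cog
        sigma_tab[i] = st.phi_B
    v0dot_tab = np.gradient(v0_tab, dt / 2, axis=0)

    def rhs(t, s):
        xb, yb, pb, vxb, vyb, ob, xf, yf, pf, vxf, vyf, of = s
        i = int(round(t / (dt / 2)))
        v0 = v0_tab[i]
        sigma = sigma_tab[i]
        v0dot = v0dot_tab[i]
        cp, sp = math.cos(pf), math.sin(pf)
        rot = np.array([[cp, -sp], [sp, cp]])
        lever = rot @ v0
        att = np.array([xf, yf]) + lever
        attdot = (np.array([vxf, vyf]) + of * np.array([-lever[1], lever[0]])
                  + rot @ v0dot)
        e = np.array([xb, yb]) - att
        edot = np.array([vxb, vyb]) - attdot
        Fp = -K * e - C * edot
        Tp = -Kp * (pb - pf - sigma) - Cp * (ob - of)
        # contact forces on the foot nodes
        xc, yc = xf + lf * cp, yf + lf * sp
        vxc, vyc = vxf - of * (yc - yf), vyf + of * (xc - xf)
        forces = []
        for (x, y, vx, vy) in [(xf, yf, vxf, vyf), (xc, yc, vxc, vyc)]:
            d = -y
            if d > 0:
                fy = max(0.0, k * d - c_n * vy)
                fx = -c_t * vx
            else:
                fx = fy = 0.0
            forces.append((fx, fy))
        (fax, fay), (fcx, fcy) = forces
        ab = (Fp + np.array([0.0, -m * G])) / m
        alb = Tp / I_B
        ff = np.array([fax + fcx - Fp[0], fay + fcy - Fp[1]])
        af = (ff + np.array([0.0, -m_f * G])) / m_f
        tf = ((xc - xf) * fcy - (yc - yf) * fcx
              - (lever[0] * Fp[1] - lever[1] * Fp[0]) - Tp)
        alf = tf / I_f
        return np.array([vxb, vyb, ob, ab[0], ab[1], alb,
                         vxf, vyf, of, af[0], af[1], alf])

    s = np.array([v0_tab[0, 0], v0_tab[0, 1], sigma_tab[0],
                  0, 0, 0, 0, 0, 0, 0, 0, 0], dtype=float)
    n = int(round(t_seg / dt))
    t = 0.0
    for _ in range(n):
        k1 = rhs(t, s)
        k2 = rhs(t + dt / 2, s + dt / 2 * k1)
        k3 = rhs(t + dt / 2, s + dt / 2 * k2)
        k4 = rhs(t + dt, s + dt * k3)
        s = s + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += dt

    ref_end = ref.data.iloc[-1]
    err = math.hypot(s[0] - ref_end.x_B, s[1] - ref_end.y_B)
    return err / morph.L_max
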