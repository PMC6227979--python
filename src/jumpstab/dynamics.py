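"""Time integration of the ground model and inverse dynamics of the perch model.

Ground model
------------
With massless legs and kinematically prescribed joints, the only dynamic
coordinates are the foot pose ``(x_f, y_f, phi_f)``: the body pose is a
known function of foot pose and time, so the whole-system Newton-Euler
equations

.. math::

    m \\ddot r_B = R_A + R_C + (0, -m g) + F_{wing}, \\qquad
    I_B \\dot\\omega_B = \\sum (r_i - r_B) \\times F_i + T_{wing}

reduce to an explicit ODE in the foot-pose coordinates (contact forces
depend on positions and velocities only).  The same ODE covers flight: with
no contact force the body follows a ballistic parabola while the foot pose
evolves to keep the prescribed joint motion -- so stutters (contact regained
after a premature toe-off) emerge naturally.  Integration is fixed-step RK4
(default 1e-5 s) with no contact event localisation; contact activation is
evaluated at every substep.

Perch model
-----------
The foot is fixed (the grip is assumed to prevent both slip and rotation
about the perch), so the body motion follows directly from the joint
trajectories and the reactions come from inverse dynamics: the net reaction
force at the perch and the grip torque the foot must supply.  The perch
point is the TMT joint (the rear-toe node of the chain).

Wing inertial loads are computed from the sinusoidal elevation/extension
kinematics of a tri-segmented wing pair relative to the shoulder; wing
weight is included in the load term so the body equations use body mass
only.  Aerodynamics is not modelled; an ``external_force(t, state)`` hook is
available for callers who wish to add it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .contact import ContactParams, ground_reactions, node_states_from_chain, normal_force, friction_force
from .kinematics import (JointTrajectorySet, _chain_core, _segment_geometry,
                         forward_kinematics, chain_derivatives)
from .morphology import MorphologyParams, WingParams


class IntegrationError(RuntimeError):
    """Raised when the fixed-step integration produces a non-finite state."""


@dataclass
class SimConfig:
    """Configuration of a simulation run."""

    dt: float = 1e-5
    t_span: tuple[float, float] | None = None
    contact: ContactParams = field(default_factory=ContactParams)
    wing: WingParams | None = None
    output_dt: float = 1e-4
    external_force: Callable | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.output_dt < self.dt:
            self.output_dt = self.dt


RESULT_COLUMNS = [
    "t", "x_f", "y_f", "phi_f", "x_B", "y_B", "phi_B", "vx_B", "vy_B", "omega_B",
    "ax_B", "ay_B", "alpha_B", "RAx", "RAy", "RCx", "RCy", "RPx", "RPy", "x_P", "T_grip",
]


@dataclass
class SimResult:
    """Uniformly sampled time histories of a ground or perch simulation.

    ``x_P`` is NaN while airborne (no normal load); ``T_grip`` is NaN in
    ground mode.  ``mode`` is ``"ground"`` or ``"perch"``.
    """

    data: pd.DataFrame
    morph: MorphologyParams
    mode: str
    meta: dict = field(default_factory=dict)

    def __getattr__(self, name):
        # column access shortcut: result.t, result.RAy, ...
        if name in RESULT_COLUMNS:
            return self.data[name].to_numpy()
        raise AttributeError(name)

    @property
    def front_toe_x(self) -> np.ndarray:
        return self.data["x_f"].to_numpy() + self.morph.l_foot * np.cos(self.data["phi_f"].to_numpy())

    @property
    def front_toe_y(self) -> np.ndarray:
        return self.data["y_f"].to_numpy() + self.morph.l_foot * np.sin(self.data["phi_f"].to_numpy())

    def to_frame(self) -> pd.DataFrame:
        return self.data.copy()


# ---------------------------------------------------------------------------
# wing inertial loads
# ---------------------------------------------------------------------------

def _quintic(u: float) -> tuple[float, float, float]:
    """Quintic smoothstep value and first two derivatives w.r.t. u, clamped."""
    if u <= 0.0:
        return 0.0, 0.0, 0.0
    if u >= 1.0:
        return 1.0, 0.0, 0.0
    s = u * u * u * (10.0 + u * (-15.0 + 6.0 * u))
    s1 = 30.0 * u * u * (1.0 - u) * (1.0 - u)
    s2 = u * (60.0 + u * (-180.0 + 120.0 * u))
    return s, s1, s2


def wing_inertial_loads(wing: WingParams, t: float, g: float = 9.81):
    """Net sagittal-plane wing load on the body at the shoulder.

    The wing pair is reduced to three point masses per side at the segment
    centres; elevation and extension both follow a C2 smoothstep over the
    upstroke period and hold thereafter.  Lateral components cancel by the
    left/right symmetry, leaving a force 2-vector and a pitch torque.  Wing
    weight is included in the returned force (gravity bookkeeping: the body
    equations of motion then use body mass only).  Accelerations are taken
    relative to the shoulder.

    Returns ``(fx, fy, torque)``.
    """
    if not wing.enabled or wing.wing_total_mass == 0.0:
        return 0.0, 0.0, 0.0
    m_seg = wing.wing_total_mass / 3.0
    T = wing.upstroke_period
    u = (t - wing.start_time) / T
    s, s1, s2 = _quintic(u)
    s1 /= T
    s2 /= T * T
    eta = wing.initial_elevation + wing.elevation_amplitude * s
    etad = wing.elevation_amplitude * s1
    etadd = wing.elevation_amplitude * s2
    e = min(1.0, wing.initial_extension + wing.extension_amplitude * s)
    ed = wing.extension_amplitude * s1
    edd = wing.extension_amplitude * s2

    l1, l2, l3 = wing.segment_lengths
    centres = (0.5 * l1, l1 + 0.5 * l2, l1 + l2 + 0.5 * l3)
    ce, se = math.cos(eta), math.sin(eta)
    fx = fy = torque = 0.0
    for c in centres:
        d = e * c
        dd = ed * c
        ddd = edd * c
        # r = d u(eta); u' = u_perp
        rx = d * ce
        ry = d * se
        ax = ddd * ce - 2.0 * dd * etad * se - d * (etadd * se + etad * etad * ce)
        ay = ddd * se + 2.0 * dd * etad * ce + d * (etadd * ce - etad * etad * se)
        fx += -m_seg * ax
        fy += -m_seg * (ay + g)
        torque += -m_seg * (rx * ay - ry * ax + g * rx)
    return fx, fy, torque


# ---------------------------------------------------------------------------
# ground model
# ---------------------------------------------------------------------------

def simulate_ground(
    morph: MorphologyParams,
    traj: JointTrajectorySet,
    config: SimConfig | None = None,
    initial_foot_pose=None,
    initial_foot_rates=(0.0, 0.0, 0.0),
) -> SimResult:
    """Integrate the ground take-off model over the trajectory domain.

    The initial foot pose defaults to flat on the contact plane with the
    rear toe at the origin, and the system starts at rest.  The run stops at
    the end of the joint-trajectory domain (or at ``config.t_span`` if that
    ends earlier).
    """
    config = config or SimConfig()
    params = config.contact
    t0, t1 = traj.domain
    if config.t_span is not None:
        t0 = max(t0, config.t_span[0])
        t1 = min(t1, config.t_span[1])
    if initial_foot_pose is None:
        initial_foot_pose = (0.0, params.plane_height, 0.0)

    m = morph.body_mass
    inv_m = 1.0 / m
    I_B = morph.body_inertia
    g = morph.g
    k = params.stiffness
    c_n = params.normal_damping(m)
    c_t = params.tangential_damping
    h_plane = params.plane_height
    l_foot = morph.l_foot
    wing = config.wing if (config.wing is not None and config.wing.enabled) else None
    ext_force = config.external_force
    eval_scalar = traj.eval_scalar
    (l1, l2, l3, l4), beta = _segment_geometry(morph)
    three_pi = 3.0 * math.pi

    # The dynamic coordinates are the 3 d.f. of the floating chain; the state
    # is carried as the body pose/rates (the foot pose is recovered from the
    # rigid chain map at every evaluation).  This makes the flight phase
    # exactly ballistic: with zero contact force RK4 integrates the constant
    # acceleration without the quadrature drift that integrating the
    # prescribed-joint terms would introduce.
    def rhs(t, s, want_diag=False):
        x_B, y_B, phi_B, vxB, vyB, omB = s
        q, qd, qdd = eval_scalar(t)
        q_hip, q_knee, q_ankle, q_tmt = q
        qd_hip, qd_knee, qd_ankle, qd_tmt = qd
        sum_q = q_hip + q_knee + q_ankle + q_tmt
        sum_qd = qd_hip + qd_knee + qd_ankle + qd_tmt
        phi_f = phi_B - sum_q - three_pi
        om_f = omB - sum_qd

        # chain vector rear toe -> CoG and its time derivative
        a1 = phi_f + q_tmt
        a2 = a1 + math.pi + q_ankle
        a3 = a2 + math.pi + q_knee
        a4 = phi_B + beta
        a1d = om_f + qd_tmt
        a2d = a1d + qd_ankle
        a3d = a2d + qd_knee
        vx_ch = vy_ch = vxd = vyd = 0.0
        for lk, ak, akd in ((l1, a1, a1d), (l2, a2, a2d), (l3, a3, a3d), (l4, a4, omB)):
            ca = math.cos(ak)
            sa = math.sin(ak)
            vx_ch += lk * ca
            vy_ch += lk * sa
            vxd += -lk * akd * sa
            vyd += lk * akd * ca
        x_f = x_B - vx_ch
        y_f = y_B - vy_ch
        vx_f = vxB - vxd
        vy_f = vyB - vyd

        # toe nodes: A = rear toe (foot origin), C = front toe
        cphi = math.cos(phi_f)
        sphi = math.sin(phi_f)
        xc = x_f + l_foot * cphi
        yc = y_f + l_foot * sphi
        vxc = vx_f - om_f * (yc - y_f)
        vyc = vy_f + om_f * (xc - x_f)

        # unilateral critically damped normal springs + bilateral tangential dampers
        da = h_plane - y_f
        fay = fax = 0.0
        if da > 0.0:
            fay = k * da - c_n * vy_f
            if fay > 0.0:
                fax = -c_t * vx_f  # friction only under positive normal load
            else:
                fay = 0.0
        dc = h_plane - yc
        fcy = fcx = 0.0
        if dc > 0.0:
            fcy = k * dc - c_n * vyc
            if fcy > 0.0:
                fcx = -c_t * vxc
            else:
                fcy = 0.0

        fx = fax + fcx
        fy = fay + fcy - m * g
        moment = ((x_f - x_B) * fay - (y_f - y_B) * fax
                  + (xc - x_B) * fcy - (yc - y_B) * fcx)
        if wing is not None:
            wfx, wfy, wtq = wing_inertial_loads(wing, t - traj.domain[0], g)
            fx += wfx
            fy += wfy
            moment += wtq  # wing load applied at the shoulder, taken at the body CoG
        if ext_force is not None:
            efx, efy, etq = ext_force(t, s)
            fx += efx
            fy += efy
            moment += etq

        alpha_B = moment / I_B
        if not want_diag:
            return (vxB, vyB, omB, fx * inv_m, fy * inv_m, alpha_B)
        diag = (x_f, y_f, phi_f, fx * inv_m, fy * inv_m, alpha_B,
                fax, fay, fcx, fcy, xc)
        return (vxB, vyB, omB, fx * inv_m, fy * inv_m, alpha_B), diag

    # a-priori stability check of the explicit fixed-step scheme: the
    # dominant eigenvalue comes from the contact dampers, with the tangential
    # damper acting through the body-height lever on the pitch inertia
    st0 = forward_kinematics(morph, traj.angles(t0), initial_foot_pose)
    h0 = st0.cog[1] - initial_foot_pose[1]
    lam = 2.0 * c_t * (h0 * h0 / I_B + 1.0 / m) + 2.0 * c_n / m
    if lam * config.dt > 2.78:  # RK4 real-axis stability limit
        raise IntegrationError(
            f"time step dt = {config.dt:g} s is outside the explicit scheme's "
            f"stability limit for this morphology/contact combination "
            f"(damping eigenvalue ~{lam:.3g} 1/s); use dt < {2.5 / lam:.2g} s. "
            "Light bodies with small pitch inertia make the tangential damper stiff.")

    dt = config.dt
    n_steps = int(round((t1 - t0) / dt))
    decim = max(1, int(round(config.output_dt / dt)))
    n_rec = n_steps // decim + 1
    rec = np.empty((n_rec, len(RESULT_COLUMNS)))

    kin0 = _chain_core(morph, [float(v) for v in traj.angles(t0)],
                       [float(v) for v in traj.rates(t0)], (0.0,) * 4,
                       tuple(float(v) for v in initial_foot_pose),
                       tuple(float(v) for v in initial_foot_rates))
    s = (kin0[0], kin0[1], kin0[2], kin0[3], kin0[4], kin0[5])
    half = 0.5 * dt
    sixth = dt / 6.0
    irec = 0
    for step in range(n_steps + 1):
        t = t0 + step * dt
        if step % decim == 0:
            _, d = rhs(t, s, want_diag=True)
            (x_f, y_f, phi_f, axB, ayB, alB, fax, fay, fcx, fcy, xc) = d
            fn = fay + fcy
            x_p = (x_f * fay + xc * fcy) / fn if fn > 0.0 else math.nan
            rec[irec] = (t, x_f, y_f, phi_f, s[0], s[1], s[2], s[3], s[4], s[5],
                         axB, ayB, alB, fax, fay, fcx, fcy, fax + fcx, fay + fcy,
                         x_p, math.nan)
            irec += 1
            if not all(math.isfinite(v) for v in s):
                raise IntegrationError(f"non-finite state at t = {t:.6f} s")
            if abs(s[1]) > 100.0 * morph.L_max or abs(phi_f) > 20.0 * math.pi:
                raise IntegrationError(
                    f"diverging state at t = {t:.6f} s (body at y = {s[1]:.3g} m, "
                    f"phi_f = {phi_f:.3g} rad); the explicit fixed-step scheme is "
                    "likely outside its stability limit -- reduce dt (light bodies "
                    "with small pitch inertia make the tangential contact damper stiff)")
        if step == n_steps:
            break
        k1 = rhs(t, s)
        s2 = tuple(si + half * ki for si, ki in zip(s, k1))
        k2 = rhs(t + half, s2)
        s3 = tuple(si + half * ki for si, ki in zip(s, k2))
        k3 = rhs(t + half, s3)
        s4 = tuple(si + dt * ki for si, ki in zip(s, k3))
        k4 = rhs(t + dt, s4)
        s = tuple(si + sixth * (a + 2.0 * (b + c) + e)
                  for si, a, b, c, e in zip(s, k1, k2, k3, k4))

    data = pd.DataFrame(rec[:irec], columns=RESULT_COLUMNS)
    meta = {"dt": dt, "output_dt": decim * dt, "t0": t0, "t1": t1,
            "stiffness": params.stiffness, "zeta": params.zeta,
            "tangential_damping": params.tangential_damping,
            "wing": wing is not None}
    return SimResult(data, morph, "ground", meta)


# ---------------------------------------------------------------------------
# perch model
# ---------------------------------------------------------------------------

def simulate_perch(
    morph: MorphologyParams,
    traj: JointTrajectorySet,
    config: SimConfig | None = None,
    foot_pose=(0.0, 0.0, 0.0),
) -> SimResult:
    """Inverse dynamics of the perch (gripping) take-off.

    The foot pose is fixed for all time; the body pose follows the joint
    trajectories by forward kinematics (no ODE), and the grip must supply
    the net reaction force and torque.  The perch point is the TMT joint,
    i.e. the rear-toe node.  Reported reactions place the whole load at the
    perch node (``R_A``); ``R_C`` is identically zero and the CoP sits at
    the perch point while the reaction has positive vertical component.
    """
    config = config or SimConfig()
    t0, t1 = traj.domain
    if config.t_span is not None:
        t0 = max(t0, config.t_span[0])
        t1 = min(t1, config.t_span[1])
    m = morph.body_mass
    I_B = morph.body_inertia
    g = morph.g
    wing = config.wing if (config.wing is not None and config.wing.enabled) else None
    x_p, y_p = float(foot_pose[0]), float(foot_pose[1])

    n = int(round((t1 - t0) / config.output_dt)) + 1
    ts = t0 + config.output_dt * np.arange(n)
    ts[-1] = min(ts[-1], t1)
    rec = np.empty((n, len(RESULT_COLUMNS)))
    for i, t in enumerate(ts):
        kin = chain_derivatives(morph, traj, foot_pose, (0.0, 0.0, 0.0), float(t))
        x_B, y_B = kin.state.cog
        axB, ayB = kin.acceleration
        vxB, vyB = kin.velocity
        if wing is not None:
            wfx, wfy, wtq = wing_inertial_loads(wing, float(t) - t0, g)
        else:
            wfx = wfy = wtq = 0.0
        rpx = m * axB - wfx
        rpy = m * (ayB + g) - wfy
        # couple about the CoG: grip torque + moment of R_P at the perch + wing torque
        t_grip = (I_B * kin.alpha
                  - ((x_p - x_B) * rpy - (y_p - y_B) * rpx)
                  - wtq)
        rec[i] = (t, x_p, y_p, foot_pose[2], x_B, y_B, kin.state.phi_B,
                  vxB, vyB, kin.omega, axB, ayB, kin.alpha,
                  rpx, rpy, 0.0, 0.0, rpx, rpy,
                  x_p if rpy > 0 else math.nan, t_grip)

    data = pd.DataFrame(rec, columns=RESULT_COLUMNS)
    meta = {"dt": config.output_dt, "output_dt": config.output_dt, "t0": t0, "t1": t1,
            "perch_point": (x_p, y_p), "wing": wing is not None}
    return SimResult(data, morph, "perch", meta)
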