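"""Planar kinematic chain and joint-angle trajectories.

Coordinate and sign conventions
-------------------------------
* Ground frame: x forward (jump direction), y up, angles anticlockwise
  positive.  The origin is conventionally placed at the rear-toe contact at
  t = 0.
* Foot pose ``(x_f, y_f, phi_f)``: position of the rear-toe node A and
  orientation of the rigid foot segment.  The front-toe node C lies a foot
  length ahead of A along the foot direction.  The TMT joint coincides with
  the rear-toe node.
* Joint angles ``q = (q_hip, q_knee, q_ankle, q_tmt)`` are the included
  angles between adjacent segments, measured anticlockwise from the distal
  to the proximal segment.  Writing ``alpha_k`` for the absolute direction of
  segment k (from its distal joint towards its proximal joint):

  .. code-block:: text

      alpha_tmt = phi_f + q_tmt
      alpha_tib = alpha_tmt + pi + q_ankle
      alpha_fem = alpha_tib + pi + q_knee
      phi_B     = alpha_fem + pi + q_hip       (body axis, hip -> head)

  so an included angle of pi means two colinear (straight) segments, and a
  vertical leg over a flat foot has ``q_tmt = q_hip = pi/2`` and
  ``q_ankle = q_knee = pi`` (body pitch zero).  Angles are radians
  internally; all file formats use degrees.

Joint motion is prescribed: trajectories are natural cubic splines through
knot samples, so angle, rate and acceleration are all available and C2
continuity holds across knots.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .morphology import MorphologyParams

JOINT_NAMES = ("hip", "knee", "ankle", "tmt")


@dataclass
class JointAngles:
    """Included joint angles (radians), anticlockwise from distal to proximal segment."""

    hip: float
    knee: float
    ankle: float
    tmt: float

    def as_array(self) -> np.ndarray:
        return np.array([self.hip, self.knee, self.ankle, self.tmt], dtype=float)

    @classmethod
    def from_array(cls, q) -> "JointAngles":
        q = np.asarray(q, dtype=float)
        if q.shape != (4,) or not np.all(np.isfinite(q)):
            raise ValueError("joint angles must be 4 finite values (hip, knee, ankle, tmt)")
        return cls(*q)


@dataclass
class ChainState:
    """Pose of every joint of the chain, plus body CoG and pitch.

    Velocities and accelerations are populated when rates are supplied to
    :func:`chain_derivatives`; otherwise they are ``None``.
    """

    rear_toe: tuple[float, float]
    front_toe: tuple[float, float]
    ankle: tuple[float, float]
    knee: tuple[float, float]
    hip: tuple[float, float]
    cog: tuple[float, float]
    phi_f: float
    phi_B: float
    cog_velocity: tuple[float, float] | None = None
    cog_acceleration: tuple[float, float] | None = None
    omega_B: float | None = None
    alpha_B: float | None = None

    @property
    def joint_positions(self) -> dict[str, tuple[float, float]]:
        return {
            "rear_toe": self.rear_toe,
            "tmt": self.rear_toe,
            "ankle": self.ankle,
            "knee": self.knee,
            "hip": self.hip,
            "cog": self.cog,
            "front_toe": self.front_toe,
        }


def _segment_geometry(morph: MorphologyParams):
    ox, oy = morph.hip_offset
    l4 = math.hypot(ox, oy)
    beta = math.atan2(oy, ox) if l4 > 0 else 0.0
    return (morph.l_tmt, morph.l_tibiotarsus, morph.l_femur, l4), beta


def _absolute_angles(phi_f, q_hip, q_knee, q_ankle, q_tmt, beta):
    a1 = phi_f + q_tmt
    a2 = a1 + math.pi + q_ankle
    a3 = a2 + math.pi + q_knee
    phi_B = a3 + math.pi + q_hip
    return a1, a2, a3, phi_B, phi_B + beta


def forward_kinematics(morph: MorphologyParams, q, foot_pose) -> ChainState:
    """Positions of all joints and the body CoG for a given foot pose.

    Parameters
    ----------
    morph : MorphologyParams
    q : JointAngles or 4-sequence
        ``(q_hip, q_knee, q_ankle, q_tmt)`` in radians.
    foot_pose : 3-sequence
        ``(x_f, y_f, phi_f)`` -- rear-toe position and foot orientation.
    """
    if isinstance(q, JointAngles):
        q_hip, q_knee, q_ankle, q_tmt = q.hip, q.knee, q.ankle, q.tmt
    else:
        q_hip, q_knee, q_ankle, q_tmt = (float(v) for v in q)
    x_f, y_f, phi_f = (float(v) for v in foot_pose)
    (l1, l2, l3, l4), beta = _segment_geometry(morph)
    a1, a2, a3, phi_B, a4 = _absolute_angles(phi_f, q_hip, q_knee, q_ankle, q_tmt, beta)

    ankle = (x_f + l1 * math.cos(a1), y_f + l1 * math.sin(a1))
    knee = (ankle[0] + l2 * math.cos(a2), ankle[1] + l2 * math.sin(a2))
    hip = (knee[0] + l3 * math.cos(a3), knee[1] + l3 * math.sin(a3))
    cog = (hip[0] + l4 * math.cos(a4), hip[1] + l4 * math.sin(a4))
    front = (x_f + morph.l_foot * math.cos(phi_f), y_f + morph.l_foot * math.sin(phi_f))
    return ChainState(
        rear_toe=(x_f, y_f), front_toe=front, ankle=ankle, knee=knee, hip=hip,
        cog=cog, phi_f=phi_f, phi_B=phi_B,
    )


class JointTrajectorySet:
    """Twice-differentiable joint-angle time histories for the four leg joints.

    Built from knot samples by natural cubic-spline interpolation (zero
    second derivative at the end knots).  Angle, rate and acceleration are
    exposed both as vectorised calls and as a fast scalar evaluator used by
    the fixed-step integrator.
    """

    def __init__(self, times, angles_rad, _angles_deg=None):
        times = np.asarray(times, dtype=float)
        angles = np.asarray(angles_rad, dtype=float)
        self._angles_deg = None if _angles_deg is None else np.asarray(_angles_deg, float)
        if times.ndim != 1 or times.size < 4:
            raise ValueError("need at least 4 knots for cubic-spline joint trajectories")
        if angles.shape != (times.size, 4):
            raise ValueError(f"angles must have shape (n, 4), got {angles.shape}")
        if not np.all(np.diff(times) > 0):
            raise ValueError("knot times must be strictly increasing")
        if not (np.all(np.isfinite(times)) and np.all(np.isfinite(angles))):
            raise ValueError("knot times and angles must be finite")
        self._times = times
        self._angles = angles
        self._spline = CubicSpline(times, angles, bc_type="natural")
        self._d1 = self._spline.derivative(1)
        self._d2 = self._spline.derivative(2)
        # flattened per-segment coefficients for the scalar fast path
        self._breaks = times.tolist()
        c = self._spline.c  # (4, nseg, 4)
        self._coef = [tuple(c[:, seg, :].T.ravel()) for seg in range(c.shape[1])]

    # -- basic queries -------------------------------------------------
    @property
    def domain(self) -> tuple[float, float]:
        return float(self._times[0]), float(self._times[-1])

    @property
    def knot_times(self) -> np.ndarray:
        return self._times.copy()

    @property
    def knot_angles(self) -> np.ndarray:
        return self._angles.copy()

    @property
    def knot_angles_deg(self) -> np.ndarray:
        """Knot angles in degrees: the original values when built from degrees
        (files are lossless), otherwise converted."""
        if self._angles_deg is not None:
            return self._angles_deg.copy()
        return np.rad2deg(self._angles)

    def _check_domain(self, t) -> None:
        t0, t1 = self.domain
        tmin = np.min(t)
        tmax = np.max(t)
        if tmin < t0 - 1e-12 or tmax > t1 + 1e-12:
            raise ValueError(f"time {tmin if tmin < t0 else tmax} outside trajectory domain [{t0}, {t1}]")

    def angles(self, t) -> np.ndarray:
        """Joint angles (rad), columns ordered (hip, knee, ankle, tmt)."""
        self._check_domain(t)
        return self._spline(t)

    def rates(self, t) -> np.ndarray:
        self._check_domain(t)
        return self._d1(t)

    def accelerations(self, t) -> np.ndarray:
        self._check_domain(t)
        return self._d2(t)

    # -- fast scalar path ----------------------------------------------
    def eval_scalar(self, t: float):
        """Angles, rates and accelerations at scalar ``t`` as three 4-tuples.

        No domain check (the integrator guarantees the domain); clamps to the
        end segments for round-off excursions.
        """
        breaks = self._breaks
        i = bisect_right(breaks, t) - 1
        if i < 0:
            i = 0
        elif i >= len(self._coef):
            i = len(self._coef) - 1
        dt = t - breaks[i]
        c = self._coef[i]
        q = []
        qd = []
        qdd = []
        for j in range(4):
            c0, c1, c2, c3 = c[4 * j:4 * j + 4]
            q.append(((c0 * dt + c1) * dt + c2) * dt + c3)
            qd.append((3.0 * c0 * dt + 2.0 * c1) * dt + c2)
            qdd.append(6.0 * c0 * dt + 2.0 * c1)
        return q, qd, qdd

    # -- construction helpers ------------------------------------------
    @classmethod
    def from_degrees(cls, times, angles_deg) -> "JointTrajectorySet":
        angles_deg = np.asarray(angles_deg, dtype=float)
        return cls(times, np.deg2rad(angles_deg), _angles_deg=angles_deg)


@dataclass
class ChainKinematics:
    """Body motion derived from the chain at one instant."""

    velocity: tuple[float, float]
    acceleration: tuple[float, float]
    omega: float
    alpha: float
    jacobian: np.ndarray  # d(body pose)/d(foot pose), 3x3
    state: ChainState


def chain_derivatives(
    morph: MorphologyParams,
    traj: JointTrajectorySet,
    foot_pose,
    foot_rates,
    t: float,
    foot_accel=(0.0, 0.0, 0.0),
) -> ChainKinematics:
    """Body velocity/acceleration and the foot-pose Jacobian at time ``t``.

    The body pose is a function of the foot pose and the prescribed joint
    angles; this returns its analytic first and second time derivatives for
    given foot-pose rates (and optional accelerations), plus the Jacobian of
    the body pose with respect to the foot pose, which is the rigid-body map
    (identity translation rows; the rotation column couples the lever arm
    from the rear toe to the CoG).

    Raises ``ValueError`` if ``t`` is outside the trajectory domain.
    """
    t0, t1 = traj.domain
    if not (t0 - 1e-12 <= t <= t1 + 1e-12):
        raise ValueError(f"t={t} outside trajectory domain [{t0}, {t1}]")
    q, qd, qdd = traj.eval_scalar(float(t))
    x_f, y_f, phi_f = (float(v) for v in foot_pose)
    vx_f, vy_f, om_f = (float(v) for v in foot_rates)
    ax_f, ay_f, al_f = (float(v) for v in foot_accel)

    core = _chain_core(morph, q, qd, qdd, (x_f, y_f, phi_f), (vx_f, vy_f, om_f))
    (x_B, y_B, phi_B, vx0, vy0, om_B, cx, cy, wx, wy, sum_qdd, state) = core

    # add the foot-acceleration contribution: r''_B = r''_f + alpha_f * w + c
    ax = ax_f + al_f * wx + cx
    ay = ay_f + al_f * wy + cy
    alpha_B = al_f + sum_qdd

    jac = np.array([[1.0, 0.0, wx], [0.0, 1.0, wy], [0.0, 0.0, 1.0]])
    return ChainKinematics(
        velocity=(vx0, vy0), acceleration=(ax, ay), omega=om_B, alpha=alpha_B,
        jacobian=jac, state=state,
    )


def _chain_core(morph, q, qd, qdd, foot_pose, foot_rates):
    """Scalar chain evaluation shared with the dynamics engine.

    Returns body pose, velocity, angular rate, the joint-driven acceleration
    remainder ``c`` (body acceleration with zero foot acceleration), the
    rotation lever ``w = (-(y_B - y_f), x_B - x_f)`` and the joint angular
    acceleration sum, plus a populated :class:`ChainState` (positions only).
    """
    q_hip, q_knee, q_ankle, q_tmt = q
    qd_hip, qd_knee, qd_ankle, qd_tmt = qd
    qdd_hip, qdd_knee, qdd_ankle, qdd_tmt = qdd
    x_f, y_f, phi_f = foot_pose
    vx_f, vy_f, om_f = foot_rates
    (l1, l2, l3, l4), beta = _segment_geometry(morph)

    a1, a2, a3, phi_B, a4 = _absolute_angles(phi_f, q_hip, q_knee, q_ankle, q_tmt, beta)
    a1d = om_f + qd_tmt
    a2d = a1d + qd_ankle
    a3d = a2d + qd_knee
    om_B = a3d + qd_hip
    a4d = om_B
    # joint-driven part of the angular accelerations (foot contribution enters linearly)
    c1dd = qdd_tmt
    c2dd = c1dd + qdd_ankle
    c3dd = c2dd + qdd_knee
    c4dd = c3dd + qdd_hip
    sum_qdd = c4dd

    lengths = (l1, l2, l3, l4)
    angs = (a1, a2, a3, a4)
    angds = (a1d, a2d, a3d, a4d)
    angdds = (c1dd, c2dd, c3dd, c4dd)

    px, py = x_f, y_f
    vx, vy = vx_f, vy_f
    cx, cy = 0.0, 0.0
    wx, wy = 0.0, 0.0
    pts = []
    for lk, ak, akd, akdd in zip(lengths, angs, angds, angdds):
        ca = math.cos(ak)
        sa = math.sin(ak)
        px += lk * ca
        py += lk * sa
        pts.append((px, py))
        vx += -lk * akd * sa
        vy += lk * akd * ca
        cx += lk * (-akdd * sa - akd * akd * ca)
        cy += lk * (akdd * ca - akd * akd * sa)
        wx += -lk * sa
        wy += lk * ca

    x_B, y_B = px, py
    front = (x_f + morph.l_foot * math.cos(phi_f), y_f + morph.l_foot * math.sin(phi_f))
    state = ChainState(
        rear_toe=(x_f, y_f), front_toe=front, ankle=pts[0], knee=pts[1], hip=pts[2],
        cog=(x_B, y_B), phi_f=phi_f, phi_B=phi_B,
        cog_velocity=(vx, vy), omega_B=om_B,
    )
    return (x_B, y_B, phi_B, vx, vy, om_B, cx, cy, wx, wy, sum_qdd, state)


def _quintic_step(u: float) -> float:
    """C2 smoothstep: 0 -> 1 with zero first and second derivatives at ends."""
    if u <= 0.0:
        return 0.0
    if u >= 1.0:
        return 1.0
    return u * u * u * (10.0 + u * (-15.0 + 6.0 * u))


def perturb_trajectory(
    traj: JointTrajectorySet,
    joint: str,
    rate_scale: float,
    window: tuple[float, float],
    blend_frac: float = 0.1,
    n_dense: int = 400,
) -> JointTrajectorySet:
    """Scale one joint's angular rate inside a time window.

    Inside ``window`` the joint's angular rate is multiplied by
    ``rate_scale``, with C1 smooth blending over a fraction ``blend_frac`` of
    the window at each edge.  The angle is continuous everywhere; before the
    window it equals the input, and after the window it differs by the
    constant offset the scaled rate accumulated (modified kinematics
    legitimately change the subsequent motion).  Other joints are untouched.
    """
    if joint not in JOINT_NAMES:
        raise ValueError(f"joint must be one of {JOINT_NAMES}, got {joint!r}")
    t0, t1 = traj.domain
    t_a, t_b = float(window[0]), float(window[1])
    if not (t0 - 1e-12 <= t_a < t_b <= t1 + 1e-12):
        raise ValueError(f"window [{t_a}, {t_b}] must lie inside trajectory domain [{t0}, {t1}]")
    jidx = JOINT_NAMES.index(joint)

    # refined knot grid: original knots plus a dense grid across the window
    dense = np.linspace(t_a, t_b, n_dense)
    times = np.unique(np.concatenate([traj.knot_times, dense]))
    angles = traj.angles(times).copy()

    if rate_scale != 1.0:
        blend = blend_frac * (t_b - t_a)

        def bump(t):
            if t <= t_a or t >= t_b:
                return 0.0
            return _quintic_step((t - t_a) / blend) * _quintic_step((t_b - t) / blend)

        # offset(t) = (s - 1) * integral_{t_a}^{t} bump * qdot  (fine-grid Simpson)
        fine = np.linspace(t_a, t_b, 4 * n_dense + 1)
        rates = traj.rates(fine)[:, jidx]
        integrand = np.array([bump(tv) for tv in fine]) * rates
        h = fine[1] - fine[0]
        cum = np.concatenate([[0.0], np.cumsum((integrand[1:] + integrand[:-1]) * 0.5 * h)])
        offset_in = (rate_scale - 1.0) * np.interp(times, fine, cum)
        offset_in[times <= t_a] = 0.0
        offset_in[times >= t_b] = (rate_scale - 1.0) * cum[-1]
        angles[:, jidx] += offset_in

    return JointTrajectorySet(times, angles)
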