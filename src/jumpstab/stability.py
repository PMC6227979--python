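"""Analytical toe-off and tipping-stability models.

Two families of results:

1. **One-dimensional toe-off.**  For a lumped body of mass ``m`` on a
   massless, vertically extensible leg of length ``L(t)``, the ground
   reaction is ``R = m g + m y''`` and contact is lost exactly when the leg
   deceleration reaches ``-g``.  Intermittent loss and regain of contact
   before maximum extension ("stutters") falls out of the same condition.
   A linear-spring leg admits a closed-form harmonic solution and shows that
   body speed peaks *before* toe-off.

2. **Planar tipping stability.**  With a finite foot spanning the rear and
   front toes, the centre of pressure (CoP) -- the point on the ground
   through which the net reaction must act for zero net moment, equivalent
   to the zero-moment point -- must stay within the foot.  Writing
   ``theta`` for the elevation of the net ground reaction (the *acceleration
   angle*), the CoP sits at

   .. math:: x_P = x_B - y_B \\cot\\theta + T_B / (\\lVert R_P \\rVert \\sin\\theta)

   which inverts into fore/aft bounds on the CoG position (dimensionless in
   units of foot length) and, dually, into an angular *stability window* of
   admissible reaction directions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

G_DEFAULT = 9.81


class ZeroReactionError(ValueError):
    """Raised when a CoP/stability query is made with (near-)zero net reaction."""


# ---------------------------------------------------------------------------
# 1-D toe-off
# ---------------------------------------------------------------------------

def reaction_1d(m: float, y_ddot: float, g: float = G_DEFAULT) -> float:
    """Ground reaction R = m g + m y'' of the 1-D massless-leg jumper."""
    if m <= 0:
        raise ValueError(f"mass must be positive, got {m}")
    return m * (g + y_ddot)


class LegExtensionProfile:
    """Leg length L(t) with first/second derivatives, optionally locking.

    ``lock_time`` models a leg that reaches maximum extension and locks
    instantaneously (infinite deceleration): beyond it the length is frozen
    at ``L(lock_time)`` and, if the system is still in contact, toe-off
    occurs exactly at the lock.
    """

    def __init__(self, L, Ldot, Lddot, domain, lock_time: float | None = None):
        self._L, self._Ld, self._Ldd = L, Ldot, Lddot
        self.domain = (float(domain[0]), float(domain[1]))
        self.lock_time = lock_time

    def length(self, t: float) -> float:
        if self.lock_time is not None and t >= self.lock_time:
            return self._L(self.lock_time)
        return self._L(t)

    def rate(self, t: float) -> float:
        if self.lock_time is not None and t >= self.lock_time:
            return 0.0
        return self._Ld(t)

    def accel(self, t: float) -> float:
        if self.lock_time is not None and t >= self.lock_time:
            return 0.0
        return self._Ldd(t)

    @classmethod
    def constant_rate(cls, L0: float, v: float, lock_time: float, t_end: float | None = None):
        """Extension at constant rate ``v`` that locks at ``lock_time``."""
        t_end = t_end if t_end is not None else 2.0 * lock_time
        return cls(lambda t: L0 + v * t, lambda t: v, lambda t: 0.0, (0.0, t_end), lock_time=lock_time)

    @classmethod
    def from_spline(cls, times, lengths):
        from scipy.interpolate import CubicSpline

        sp = CubicSpline(np.asarray(times, float), np.asarray(lengths, float), bc_type="natural")
        d1, d2 = sp.derivative(1), sp.derivative(2)
        return cls(lambda t: float(sp(t)), lambda t: float(d1(t)), lambda t: float(d2(t)),
                   (float(times[0]), float(times[-1])))


@dataclass
class OneDResult:
    """Time history of the 1-D jump with contact flags and toe-off events."""

    t: np.ndarray
    y: np.ndarray
    ydot: np.ndarray
    reaction: np.ndarray
    in_contact: np.ndarray
    toe_off_times: list[float]
    touchdown_times: list[float]

    @property
    def n_contact_intervals(self) -> int:
        flags = self.in_contact.astype(int)
        starts = int(flags[0] == 1) + int(np.sum(np.diff(flags) == 1))
        return starts


def simulate_1d(profile: LegExtensionProfile, m: float, dt: float = 1e-5,
                g: float = G_DEFAULT) -> OneDResult:
    """March the 1-D toe-off model through the profile's time domain.

    While in contact ``y = L`` and ``R = m(g + L'')``; toe-off triggers at the
    first instant ``R <= 0`` (or at a declared lock); in flight the body is
    ballistic and contact is regained when the ballistic height falls back to
    the current leg length (a stutter), with the body velocity resetting to
    the leg rate -- the massless-leg idealisation of an inelastic landing.
    Multiple toe-offs are permitted.
    """
    if m <= 0:
        raise ValueError("mass must be positive")
    t0, t1 = profile.domain
    n = int(round((t1 - t0) / dt)) + 1
    ts = t0 + dt * np.arange(n)
    y = np.empty(n)
    yd = np.empty(n)
    R = np.empty(n)
    contact = np.empty(n, dtype=bool)
    toe_offs: list[float] = []
    touchdowns: list[float] = []

    if profile.length(t0) <= 0:
        raise ValueError("leg length must be positive throughout the domain")

    in_contact = True
    y_to = v_to = t_to = 0.0  # flight initial conditions
    for i, t in enumerate(ts):
        L = profile.length(t)
        if L <= 0:
            raise ValueError(f"leg length must stay positive; L({t}) = {L}")
        if in_contact:
            acc = profile.accel(t)
            locked = profile.lock_time is not None and t >= profile.lock_time
            if acc <= -g or locked:
                # refine the toe-off instant within the previous step
                if locked:
                    t_star = profile.lock_time
                else:
                    t_prev = ts[i - 1] if i > 0 else t
                    f = lambda tv: profile.accel(tv) + g
                    t_star = brentq(f, t_prev, t) if (i > 0 and f(t_prev) > 0 > f(t)) else t
                eps = 1e-12
                y_to = profile.length(max(t_star - eps, t0))
                v_to = profile.rate(max(t_star - eps, t0))
                t_to = t_star
                toe_offs.append(t_star)
                in_contact = False
        if in_contact:
            y[i] = L
            yd[i] = profile.rate(t)
            R[i] = m * (g + profile.accel(t))
            contact[i] = True
        else:
            tau = t - t_to
            yf = y_to + v_to * tau - 0.5 * g * tau * tau
            vf = v_to - g * tau
            # the 1e-10 m guard ignores round-off grazing right after toe-off
            if yf <= L - 1e-10 and tau > 0:
                # regained contact: refine touchdown where ballistic y meets L
                f = lambda tv: (y_to + v_to * (tv - t_to) - 0.5 * g * (tv - t_to) ** 2) - profile.length(tv)
                t_prev = ts[i - 1] if i > 0 else t
                try:
                    t_td = brentq(f, max(t_prev, t_to + dt * 1e-3), t)
                except ValueError:
                    t_td = t
                touchdowns.append(t_td)
                in_contact = True
                y[i] = L
                yd[i] = profile.rate(t)
                R[i] = m * (g + profile.accel(t))
                contact[i] = True
            else:
                y[i] = yf
                yd[i] = vf
                R[i] = 0.0
                contact[i] = False
    return OneDResult(ts, y, yd, R, contact, toe_offs, touchdowns)


@dataclass
class SpringLegResult:
    took_off: bool
    toe_off_time: float | None
    toe_off_speed: float | None
    peak_speed_time: float | None
    peak_speed: float | None
    omega: float


def spring_leg_takeoff(m: float, k: float, d: float, g: float = G_DEFAULT) -> SpringLegResult:
    """Closed-form harmonic solution of the spring-leg jumper.

    The body starts at rest with the spring (natural length ``L0``)
    compressed by ``d``; motion obeys ``m y'' = k (L0 - y) - m g``.  Toe-off
    occurs when the spring force reaches zero (natural length); peak body
    speed occurs earlier, at compression ``m g / k``.  If the initial elastic
    energy cannot lift the body to the natural length (``k d <= 2 m g``) the
    result is flagged as no-toe-off (at the marginal equilibrium ``k d = m g``
    the body never even starts to rise).
    """
    if m <= 0 or k <= 0 or d <= 0:
        raise ValueError("m, k, d must all be positive")
    omega = math.sqrt(k / m)
    amplitude = d - m * g / k  # oscillation amplitude about the equilibrium point
    if amplitude <= 0 or k * d <= 2 * m * g:
        return SpringLegResult(False, None, None, None, None, omega)
    t_peak = math.pi / (2.0 * omega)  # body passes the equilibrium point
    v_peak = amplitude * omega
    cosval = -(m * g / k) / amplitude
    t_off = math.acos(cosval) / omega
    v_off = math.sqrt(k * d * d / m - 2.0 * g * d)
    return SpringLegResult(True, t_off, v_off, t_peak, v_peak, omega)


def spring_leg_trajectory(m: float, k: float, d: float, t, g: float = G_DEFAULT):
    """Closed-form height history y(t) of the spring-leg jumper while in contact."""
    omega = math.sqrt(k / m)
    t = np.asarray(t, dtype=float)
    # y measured from the natural length L0: y - L0 = -mg/k - A cos(omega t)
    return -(m * g / k) - (d - m * g / k) * np.cos(omega * t)


# ---------------------------------------------------------------------------
# Planar CoP / tipping framework
# ---------------------------------------------------------------------------

def acceleration_angle(x_ddot: float, y_ddot: float, g: float = G_DEFAULT,
                       tol: float = 1e-12) -> float:
    """Elevation angle of the net ground reaction, theta = atan2(y'' + g, x'').

    The net reaction per unit mass is ``(x'', y'' + g)``; in freefall this
    vanishes and no angle is defined (:class:`ZeroReactionError`).  A static
    stance gives theta = pi/2 (vertical reaction).
    """
    rx = x_ddot
    ry = y_ddot + g
    if math.hypot(rx, ry) <= tol * g:
        raise ZeroReactionError("net reaction is zero (freefall): acceleration angle undefined")
    return math.atan2(ry, rx)


def cop_x(x_B: float, y_B: float, theta: float, T_B: float, R_mag: float) -> float:
    """Horizontal CoP position x_P = x_B - y_B cot(theta) + T_B/(R sin theta).

    ``T_B`` is the applied body torque (nose-up positive) and ``R_mag`` the
    net reaction magnitude.  A purely horizontal reaction (sin theta = 0) has
    no ground intercept and raises ``ValueError``; zero reaction raises
    :class:`ZeroReactionError`.
    """
    if R_mag <= 0:
        raise ZeroReactionError("CoP undefined for zero net reaction")
    s = math.sin(theta)
    if abs(s) < 1e-12:
        raise ValueError("CoP undefined for a purely horizontal reaction (sin theta = 0)")
    return x_B - y_B * math.cos(theta) / s + T_B / (R_mag * s)


@dataclass
class StabilityBounds:
    """Dimensionless fore/aft bounds on the CoG position (units of foot length)."""

    x_aft: float
    x_fore: float
    theta: float
    T_prime: float
    y_prime: float
    bounded: bool = True


def cog_bounds(theta: float, T_prime: float, y_prime: float) -> StabilityBounds:
    """Dimensionless CoG bounds: x'_aft = y'/tan(theta) - T'/sin(theta); x'_fore = x'_aft + 1.

    ``T' = T_B / (||R_P|| x_C)`` and ``y' = y_B / x_C``.  The window between
    the bounds always has unit (foot-length) width.  At theta in {0, pi} the
    bounds are unbounded and flagged.
    """
    if y_prime <= 0:
        raise ValueError("y_prime must be positive")
    if not (0 < theta < math.pi):
        return StabilityBounds(math.nan, math.nan, theta, T_prime, y_prime, bounded=False)
    s = math.sin(theta)
    x_aft = y_prime * math.cos(theta) / s - T_prime / s
    return StabilityBounds(x_aft, x_aft + 1.0, theta, T_prime, y_prime)


@dataclass
class StabilityWindow:
    """Angular sector of reaction directions that keep the CoP within the foot."""

    theta_lo: float
    theta_hi: float
    degenerate: bool = False

    @property
    def width(self) -> float:
        return self.theta_hi - self.theta_lo

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.theta_lo + self.theta_hi)

    def contains(self, theta: float, tol: float = 0.0) -> bool:
        return self.theta_lo - tol <= theta <= self.theta_hi + tol


def _arccot(z: float) -> float:
    """arccot into (0, pi)."""
    return math.atan2(1.0, z)


def stability_window(x_B: float, y_B: float, x_C: float, T_B: float, R_mag: float,
                     grid_deg: float = 0.1, tol: float = 1e-9) -> StabilityWindow | None:
    """Reaction directions theta in (0, pi) for which 0 <= x_P(theta) <= x_C.

    Found by dense angular sampling (default 0.1 degree) with bisection
    refinement of the boundaries to ``tol`` radians (the applied-torque term
    makes the boundary equation transcendental).  For zero torque this
    matches the closed form ``[arccot(x_B / y_B), arccot((x_B - x_C) / y_B)]``.
    Returns ``None`` when no direction is admissible; a point contact
    (``x_C = 0``) yields a degenerate (zero-width) window.
    """
    if R_mag <= 0:
        raise ZeroReactionError("stability window undefined for zero net reaction")
    if x_C < 0:
        raise ValueError("foot length x_C must be >= 0")
    if y_B <= 0:
        raise ValueError("stability queries require the CoG above the ground (y_B > 0)")
    tau = T_B / R_mag

    def xp(th: float) -> float:
        s = math.sin(th)
        return x_B - y_B * math.cos(th) / s + tau / s

    if x_C == 0.0:
        # degenerate: solve x_P(theta) = 0
        thetas = np.deg2rad(np.arange(grid_deg, 180.0, grid_deg))
        vals = np.array([xp(th) for th in thetas])
        sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
        if sign_change.size == 0:
            return None
        i = sign_change[0]
        root = brentq(xp, thetas[i], thetas[i + 1], xtol=tol)
        return StabilityWindow(root, root, degenerate=True)

    def admissible(th: float) -> bool:
        v = xp(th)
        return 0.0 <= v <= x_C

    thetas = np.deg2rad(np.arange(grid_deg, 180.0, grid_deg))
    flags = np.array([admissible(th) for th in thetas])
    if not flags.any():
        return None
    # longest contiguous admissible run (the window can in principle be
    # disconnected for extreme torques; the dominant sector is returned)
    padded = np.concatenate([[0], flags.astype(int), [0]])
    edges = np.diff(padded)
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0] - 1
    runs = ends - starts
    j = int(np.argmax(runs))
    i0, i1 = int(starts[j]), int(ends[j])

    def refine(lo, hi, f):
        """Bisect the admissibility boundary between an inadmissible lo and admissible hi."""
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if f(mid):
                hi = mid
            else:
                lo = mid
            if hi - lo < tol:
                break
        return hi

    theta_lo = thetas[i0] if i0 == 0 else refine(thetas[i0 - 1], thetas[i0], admissible)
    if i1 == len(thetas) - 1:
        theta_hi = thetas[i1]
    else:
        # mirror: walk from admissible thetas[i1] up to inadmissible thetas[i1+1]
        lo, hi = thetas[i1], thetas[i1 + 1]
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if admissible(mid):
                lo = mid
            else:
                hi = mid
            if hi - lo < tol:
                break
        theta_hi = lo
    return StabilityWindow(float(theta_lo), float(theta_hi))


@dataclass
class StabilityMapGrid:
    """Tabulated CoG bounds over an (acceleration angle, torque level) grid."""

    table: pd.DataFrame  # columns theta_deg, T_prime, x_aft, x_fore
    y_prime: float

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def stability_map(theta_deg, torque_levels, y_prime: float) -> StabilityMapGrid:
    """Tabulate :func:`cog_bounds` over acceleration angles and torque levels.

    ``theta_deg`` is a sequence of acceleration angles in degrees within
    (0, 90]; ``torque_levels`` a sequence of dimensionless torques T'.
    """
    theta_deg = np.asarray(theta_deg, dtype=float)
    if np.any(theta_deg <= 0) or np.any(theta_deg > 90):
        raise ValueError("stability-map angles must lie in (0, 90] degrees")
    rows = []
    for tp in np.asarray(torque_levels, dtype=float):
        for thd in theta_deg:
            b = cog_bounds(math.radians(thd), float(tp), y_prime)
            rows.append((thd, float(tp), b.x_aft, b.x_fore))
    table = pd.DataFrame(rows, columns=["theta_deg", "T_prime", "x_aft", "x_fore"])
    return StabilityMapGrid(table, y_prime)


def solve_aft_bound_angle(x_aft_target: float, y_prime: float, T_prime: float = 0.0,
                          tol: float = 1e-12) -> float:
    """Acceleration angle (radians) at which x'_aft equals a target, by bisection.

    For y' = 1, T' = 0 and target 1 (aft bound at the front toe) this
    recovers the 45-degree threshold below which the stable CoG range lies
    entirely beyond the foot.
    """
    f = lambda th: cog_bounds(th, T_prime, y_prime).x_aft - x_aft_target
    lo, hi = math.radians(0.5), math.radians(179.5)
    flo = f(lo)
    fhi = f(hi)
    if flo * fhi > 0:
        raise ValueError("target aft bound not bracketed in (0, pi)")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(lo) * f(mid) <= 0:
            hi = mid
        else:
            lo = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)
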