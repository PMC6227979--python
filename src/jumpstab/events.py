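"""Take-off phase events and performance/stability metrics.

Events follow the canonical ground take-off sequence: *crouch* (the CoG
minimum), *rear toe-off* (the foot stops acting as a supporting base),
possible *stutters* (intermittent loss and regain of all ground contact
before the final toe-off), *tipping onset* (sustained single-node contact
with growing foot rotation) and *final toe-off* (the first time after which
both contact normal forces remain zero).  Force comparisons use a tolerance
``tol_force`` (default one thousandth of body weight) and a debounce time
to ignore single-sample chatter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import SimResult
from .morphology import MorphologyParams

EVENT_KINDS = ("crouch", "rear_toe_off", "stutter_start", "stutter_end",
               "tipping_onset", "final_toe_off")


@dataclass
class EventRecord:
    kind: str
    time: float
    detail: dict = field(default_factory=dict)


@dataclass
class TakeoffSummary:
    takeoff_time: float
    takeoff_speed: float
    trajectory_angle_deg: float
    pitch_rate: float
    impulse_x: float
    impulse_y: float
    peak_force_norm: float
    peak_grip_torque_norm: float | None
    stable_angle_extension_deg: float | None


def _default_tol(result: SimResult) -> float:
    return 1e-3 * result.morph.weight


def final_toe_off_time(result: SimResult, tol_force: float | None = None) -> float | None:
    """First time after which both contact normal forces remain zero.

    Refined below the output sampling interval by linearly interpolating the
    decaying total normal force to zero (the compliant contact unloads with
    finite slope).  Returns ``None`` if contact persists to the end of the
    run or never occurs.
    """
    tol = tol_force if tol_force is not None else _default_tol(result)
    total = result.RAy + result.RCy
    t = result.t
    loaded = total > tol
    if not loaded.any():
        return None
    i_last = int(np.nonzero(loaded)[0][-1])
    if i_last == len(t) - 1:
        return None  # still in contact at the end of the run
    f0, f1 = total[i_last], total[i_last + 1]
    frac = f0 / (f0 - f1) if f0 > f1 else 1.0
    return float(t[i_last] + frac * (t[i_last + 1] - t[i_last]))


def detect_events(result: SimResult, tol_force: float | None = None,
                  debounce: float = 1e-3) -> list[EventRecord]:
    """Detect the take-off phase events of a simulation run."""
    tol = tol_force if tol_force is not None else _default_tol(result)
    t = result.t
    if result.mode == "perch":
        # the grip never releases: only the crouch is a meaningful event
        y_B = result.y_B
        i_crouch = int(np.argmin(y_B))
        return [EventRecord("crouch", float(t[i_crouch]), {"y_B": float(y_B[i_crouch])})]
    ray = result.RAy
    rcy = result.RCy
    rear = ray > tol
    front = rcy > tol
    any_contact = rear | front
    events: list[EventRecord] = []
    if not any_contact.any():
        warnings.warn("no ground contact in the entire run; no events detected")
        return events

    t_off = final_toe_off_time(result, tol)
    i_end = len(t) - 1 if t_off is None else int(np.searchsorted(t, t_off))

    # crouch: CoG minimum before final toe-off (earliest sample on ties)
    y_B = result.y_B
    i_crouch = int(np.argmin(y_B[: i_end + 1]))
    events.append(EventRecord("crouch", float(t[i_crouch]), {"y_B": float(y_B[i_crouch])}))

    if t_off is not None:
        events.append(EventRecord("final_toe_off", t_off, {}))
        # rear toe-off: last downward crossing of the rear normal force
        down = np.nonzero(rear[:-1] & ~rear[1:])[0]
        down = down[t[down] <= t_off]
        if down.size:
            i = int(down[-1])
            events.append(EventRecord("rear_toe_off", float(t[i + 1]), {"node": "rear"}))

    # stutters: both normals below tol, regaining contact afterwards
    airborne = ~any_contact
    i = 0
    n = len(t)
    while i < n:
        if airborne[i]:
            j = i
            while j < n and airborne[j]:
                j += 1
            if j < n and (t[j - 1] - t[i]) + (t[1] - t[0]) >= debounce:
                # interval ends with contact regained -> a stutter
                events.append(EventRecord("stutter_start", float(t[i]), {}))
                events.append(EventRecord("stutter_end", float(t[j]), {}))
            i = j
        else:
            i += 1

    # tipping onset: sustained single-node contact with growing foot rotation
    single = rear ^ front
    phi_f = result.phi_f
    with np.errstate(invalid="ignore"):
        phif_rate = np.gradient(phi_f, t)
    i = 0
    while i < n:
        if single[i] and (t_off is None or t[i] < t_off):
            j = i
            while j < n and single[j]:
                j += 1
            if t[j - 1] - t[i] >= debounce:
                k = min(n - 1, int(np.searchsorted(t, t[i] + debounce)))
                if abs(phif_rate[k]) > abs(phif_rate[i]):
                    node = "rear" if rear[i] else "front"
                    events.append(EventRecord("tipping_onset", float(t[i]), {"node": node}))
                    break
            i = j
        else:
            i += 1

    events.sort(key=lambda e: e.time)
    return events


def cop_trace(result: SimResult) -> pd.DataFrame:
    """Centre-of-pressure time series with NaN gaps while airborne.

    In perch mode the CoP remains at the perch point for as long as the
    reaction points upward (the grip constraint pins the foot).
    """
    return result.data[["t", "x_P"]].copy()


def takeoff_summary(result: SimResult, morph: MorphologyParams | None = None,
                    tol_force: float | None = None,
                    disengage_time: float | None = None) -> TakeoffSummary:
    """Take-off performance metrics of a run.

    For a ground run the reference instant is the final toe-off (an error if
    none occurred).  For a perch run -- where the model never loses contact
    -- the reference is the toe-disengagement instant: by default the last
    time the vertical reaction still reaches body weight (the toes start to
    release as the grip unloads late in the extension), overridable with
    ``disengage_time``.  At that instant the *stable-angle extension*
    is reported: the angle between the actual net-acceleration direction
    (held admissible by the grip torque) and the zero-torque stability
    direction through the perch point.
    """
    morph = morph or result.morph
    t = result.t
    if result.mode == "ground":
        t_ref = final_toe_off_time(result, tol_force)
        if t_ref is None:
            raise ValueError("no final toe-off in this run; cannot summarise take-off")
        stable_ext = None
    else:
        if disengage_time is not None:
            t_ref = float(disengage_time)
        else:
            # toes start releasing as the grip unloads: first time after the
            # peak vertical reaction that it falls back through body weight
            rpy = result.RPy
            ipk = int(np.argmax(rpy))
            below = np.nonzero(rpy[ipk:] < morph.weight)[0]
            if rpy[ipk] > morph.weight and below.size:
                t_ref = float(t[ipk + below[0] - 1])
            else:
                t_ref = float(t[0] + 0.7 * (t[-1] - t[0]))
        x_B = np.interp(t_ref, t, result.x_B)
        y_B = np.interp(t_ref, t, result.y_B)
        rpx = np.interp(t_ref, t, result.RPx)
        rpy = np.interp(t_ref, t, result.RPy)
        x_p, y_p = result.meta["perch_point"]
        if math.hypot(rpx, rpy) < 1e-6 * morph.weight:
            theta_act = math.nan
        else:
            theta_act = math.atan2(rpy, rpx)  # direction of the net reaction
        theta_zero = math.atan2(y_B - y_p, x_B - x_p)
        stable_ext = abs(math.degrees(theta_act - theta_zero))

    vx = float(np.interp(t_ref, t, result.vx_B))
    vy = float(np.interp(t_ref, t, result.vy_B))
    omega = float(np.interp(t_ref, t, result.omega_B))
    speed = math.hypot(vx, vy)
    angle = math.degrees(math.atan2(vy, vx))

    mask = t <= t_ref
    imp_x = float(np.trapezoid(result.RPx[mask], t[mask]))
    imp_y = float(np.trapezoid(result.RPy[mask], t[mask]))
    peak_force = float(np.nanmax(result.RPy)) / morph.weight
    if result.mode == "perch":
        grip = float(np.nanmax(np.abs(result.T_grip))) / (morph.weight * morph.L_max)
    else:
        grip = None
    return TakeoffSummary(
        takeoff_time=float(t_ref), takeoff_speed=speed, trajectory_angle_deg=angle,
        pitch_rate=omega, impulse_x=imp_x, impulse_y=imp_y,
        peak_force_norm=peak_force, peak_grip_torque_norm=grip,
        stable_angle_extension_deg=stable_ext,
    )


def normalize(result: SimResult, morph: MorphologyParams | None = None,
              t_toeoff: float | None = None) -> pd.DataFrame:
    """Dimensionless histories: t/T_toe-off, F/(m g), T/(m g L_max), displacements/L_max.

    Displacements are measured from the first sample.  ``t_toeoff`` defaults
    to the simulated final toe-off (ground) or the end of the run (perch);
    the simulated toe-off is used because the experimental visual definition
    has no counterpart in the model.
    """
    morph = morph or result.morph
    if t_toeoff is None:
        if result.mode == "ground":
            t_toeoff = final_toe_off_time(result)
            if t_toeoff is None:
                raise ValueError("no final toe-off; pass t_toeoff explicitly")
        else:
            t_toeoff = float(result.t[-1])
    w = morph.weight
    L = morph.L_max
    t = result.t
    out = pd.DataFrame({
        "t_norm": (t - t[0]) / (t_toeoff - t[0]),
        "Fx_norm": result.RPx / w,
        "Fy_norm": result.RPy / w,
        "T_grip_norm": result.T_grip / (w * L),
        "x_B_norm": (result.x_B - result.x_B[0]) / L,
        "y_B_norm": (result.y_B - result.y_B[0]) / L,
        "phi_B": result.phi_B,
    })
    return out
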