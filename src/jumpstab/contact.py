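"""Unilateral compliant ground contact at the toe nodes.

Normal contact at each toe node is a unilateral critically damped spring:
it can push (positive y) but never pull, and switches off entirely when the
node is above the contact plane.  The damping coefficient is
``c = 2 zeta sqrt(k m_eff)`` with the total system mass as the effective
mass (the only inertia in the massless-leg model).  Horizontal "friction"
is an overdamped bilateral damper active while the node carries normal load --
not a Coulomb stick-slip model; the residual lateral drift it allows is a
quantified model property (bounded to ~1% of toe length at the nominal
damping of 1e3 N s/m).

Named stiffness presets follow common values from the gait/robotics
literature: soft = 2 kN/m, firm = 40 kN/m, hard = 80 kN/m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .kinematics import ChainState
from .morphology import MorphologyParams

STIFFNESS_PRESETS = {"soft": 2e3, "firm": 4e4, "hard": 8e4}


@dataclass
class ContactParams:
    """Per-node contact law parameters."""

    stiffness: float = STIFFNESS_PRESETS["firm"]
    zeta: float = 1.0
    tangential_damping: float = 1e3
    plane_height: float = 0.0

    def __post_init__(self) -> None:
        if isinstance(self.stiffness, str):
            try:
                self.stiffness = STIFFNESS_PRESETS[self.stiffness]
            except KeyError:
                raise ValueError(
                    f"unknown stiffness preset {self.stiffness!r}; "
                    f"choose from {sorted(STIFFNESS_PRESETS)}"
                ) from None
        if self.stiffness <= 0:
            raise ValueError("contact stiffness must be positive")
        if self.zeta < 0 or self.tangential_damping < 0:
            raise ValueError("damping coefficients must be >= 0")

    def normal_damping(self, m_eff: float) -> float:
        return 2.0 * self.zeta * math.sqrt(self.stiffness * m_eff)

    @classmethod
    def from_config(cls, cfg: dict) -> "ContactParams":
        cfg = dict(cfg)
        return cls(**cfg)


@dataclass
class ContactNodeState:
    """Kinematic state of one toe node."""

    x: float
    y: float
    vx: float
    vy: float

    def penetration(self, plane_height: float) -> float:
        return plane_height - self.y


def normal_force(delta: float, delta_dot: float, params: ContactParams, m_eff: float) -> float:
    """Unilateral critically damped spring force.

    ``F = max(0, k delta + c delta_dot)`` while penetrating (``delta > 0``),
    zero otherwise; the clamp makes the contact strictly unilateral even when
    rapid withdrawal would put the spring-damper in tension.
    """
    if m_eff <= 0:
        raise ValueError("effective mass must be positive")
    if delta <= 0:
        return 0.0
    f = params.stiffness * delta + params.normal_damping(m_eff) * delta_dot
    return f if f > 0.0 else 0.0


def friction_force(x_dot: float, active: bool, c_t: float) -> float:
    """Bilateral tangential damper: F_x = -c_t x_dot while in contact, else 0."""
    if not active:
        return 0.0
    return -c_t * x_dot


@dataclass
class GroundReactions:
    """Per-node and net ground reactions, with the resulting CoP."""

    R_A: tuple[float, float]
    R_C: tuple[float, float]
    R_P: tuple[float, float]
    x_P: float | None  # undefined (None) when no normal load


def node_states_from_chain(state: ChainState, foot_rates) -> tuple[ContactNodeState, ContactNodeState]:
    """Toe-node kinematics from the chain state and foot-pose rates."""
    vx_f, vy_f, om_f = foot_rates
    xa, ya = state.rear_toe
    xc, yc = state.front_toe
    # front node velocity includes the foot's rigid rotation about the rear toe
    vxc = vx_f - om_f * (yc - ya)
    vyc = vy_f + om_f * (xc - xa)
    return ContactNodeState(xa, ya, vx_f, vy_f), ContactNodeState(xc, yc, vxc, vyc)


def ground_reactions(state: ChainState, foot_rates, params: ContactParams,
                     m_eff: float) -> GroundReactions:
    """Reactions at the rear (A) and front (C) toe nodes and the net CoP.

    The CoP is the normal-force-weighted mean of the loaded node positions,
    ``x_P = (x_A R_Ay + x_C R_Cy) / (R_Ay + R_Cy)``, defined only while the
    total normal load is positive.
    """
    node_a, node_c = node_states_from_chain(state, foot_rates)
    forces = []
    for node in (node_a, node_c):
        delta = node.penetration(params.plane_height)
        fy = normal_force(delta, -node.vy, params, m_eff)
        # friction needs a positive normal load, not merely penetration:
        # an unloaded (clamped) contact cannot drag the foot
        fx = friction_force(node.vx, fy > 0.0, params.tangential_damping)
        forces.append((fx, fy))
    (fax, fay), (fcx, fcy) = forces
    total_normal = fay + fcy
    if total_normal > 0.0:
        x_p = (node_a.x * fay + node_c.x * fcy) / total_normal
    else:
        x_p = None
    return GroundReactions((fax, fay), (fcx, fcy), (fax + fcx, fay + fcy), x_p)
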