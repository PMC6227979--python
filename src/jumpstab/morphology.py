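"""Morphology of the planar jumper: masses, inertia, segment lengths.

The jumper is a planar chain standing on a rigid toe segment (the *functional
foot*, spanning the rear-toe and front-toe contact points) with three leg
segments above it -- tarsometatarsus, tibiotarsus and femur -- joined by
revolute joints at the TMT, ankle, knee and hip.  All mass is lumped in the
body (legs are massless); the body pitch inertia may be given directly or
derived from a uniform prolate-spheroid model of the trunk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


def body_inertia_spheroid(mass: float, cross_section_area: float, slenderness: float) -> float:
    """Transverse (pitch-axis) inertia of a uniform prolate spheroid.

    The trunk is modelled as a prolate spheroid with semi-minor axis
    ``b = sqrt(area / pi)`` and semi-major axis ``a = slenderness * b``
    (slenderness = length/width ratio).  The transverse inertia of a uniform
    spheroid is ``I = m (a^2 + b^2) / 5``.

    Parameters
    ----------
    mass : float
        Body mass in kg.
    cross_section_area : float
        Maximum cross-sectional area of the trunk in m^2 (typically supplied
        by an allometric model).
    slenderness : float
        Length/width ratio of the trunk (dimensionless, ~2 for a bird trunk).

    Returns
    -------
    float
        Pitch-axis moment of inertia in kg m^2.
    """
    if mass <= 0 or cross_section_area <= 0 or slenderness <= 0:
        raise ValueError(
            "mass, cross_section_area and slenderness must all be positive; got "
            f"mass={mass}, cross_section_area={cross_section_area}, slenderness={slenderness}"
        )
    b = math.sqrt(cross_section_area / math.pi)
    a = slenderness * b
    return mass * (a * a + b * b) / 5.0


@dataclass
class MorphologyParams:
    """Geometric and inertial parameters of the planar jumper.

    Lengths in metres, mass in kg, inertia in kg m^2.  ``hip_offset`` is the
    position of the body centre of gravity relative to the hip joint, in the
    body frame (x toward the head, y dorsal); it defaults to zero (CoG at the
    hip).
    """

    body_mass: float
    body_inertia: float
    l_foot: float
    l_tmt: float
    l_tibiotarsus: float
    l_femur: float
    hip_offset: tuple[float, float] = (0.0, 0.0)
    g: float = 9.81

    def __post_init__(self) -> None:
        for name in ("body_mass", "body_inertia", "l_foot", "l_tmt", "l_tibiotarsus", "l_femur"):
            value = getattr(self, name)
            if not (value > 0):
                raise ValueError(f"{name} must be positive, got {value}")
        self.hip_offset = (float(self.hip_offset[0]), float(self.hip_offset[1]))

    @property
    def L_max(self) -> float:
        """Maximum leg length: the sum of the four leg segment lengths."""
        return self.l_foot + self.l_tmt + self.l_tibiotarsus + self.l_femur

    @property
    def weight(self) -> float:
        return self.body_mass * self.g

    @classmethod
    def from_config(cls, cfg: dict) -> "MorphologyParams":
        """Build from a plain config mapping.

        The body inertia may be given directly (``body_inertia``) or as a
        spheroid spec ``{"slenderness": ..., "cross_section_area": ...}``
        under the key ``spheroid``.
        """
        cfg = dict(cfg)
        if "body_inertia" not in cfg:
            try:
                sph = cfg.pop("spheroid")
            except KeyError:
                raise KeyError("config needs either 'body_inertia' or a 'spheroid' spec") from None
            cfg["body_inertia"] = body_inertia_spheroid(
                cfg["body_mass"], sph["cross_section_area"], sph["slenderness"]
            )
        known = {"body_mass", "body_inertia", "l_foot", "l_tmt", "l_tibiotarsus", "l_femur", "hip_offset", "g"}
        unknown = set(cfg) - known
        if unknown:
            raise KeyError(f"unknown morphology config keys: {sorted(unknown)}")
        if "hip_offset" in cfg:
            cfg["hip_offset"] = tuple(cfg["hip_offset"])
        return cls(**cfg)

    def to_config(self) -> dict:
        return {
            "body_mass": self.body_mass,
            "body_inertia": self.body_inertia,
            "l_foot": self.l_foot,
            "l_tmt": self.l_tmt,
            "l_tibiotarsus": self.l_tibiotarsus,
            "l_femur": self.l_femur,
            "hip_offset": list(self.hip_offset),
            "g": self.g,
        }


@dataclass
class WingParams:
    """Sinusoidal wing-pair model used for inertial (not aerodynamic) loads.

    ``wing_total_mass`` is the combined mass of both wings, split equally
    over three forelimb segments with each segment's mass lumped at its
    geometric centre.  The wing starts fully flexed and extends to full
    length at the end of the upstroke while elevating sinusoidally.
    """

    wing_total_mass: float = 0.0
    segment_lengths: tuple[float, float, float] = (0.03, 0.03, 0.03)
    upstroke_period: float = 0.1
    elevation_amplitude: float = math.radians(80.0)
    extension_amplitude: float = 0.8
    initial_elevation: float = math.radians(-20.0)
    initial_extension: float = 0.2
    start_time: float = 0.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.wing_total_mass < 0:
            raise ValueError("wing_total_mass must be >= 0")
        if self.upstroke_period <= 0:
            raise ValueError("upstroke_period must be > 0")

    @classmethod
    def from_config(cls, cfg: dict) -> "WingParams":
        cfg = dict(cfg)
        if "segment_lengths" in cfg:
            cfg["segment_lengths"] = tuple(cfg["segment_lengths"])
        return cls(**cfg)

    def to_config(self) -> dict:
        return {
            "wing_total_mass": self.wing_total_mass,
            "segment_lengths": list(self.segment_lengths),
            "upstroke_period": self.upstroke_period,
            "elevation_amplitude": self.elevation_amplitude,
            "extension_amplitude": self.extension_amplitude,
            "initial_elevation": self.initial_elevation,
            "initial_extension": self.initial_extension,
            "start_time": self.start_time,
            "enabled": self.enabled,
        }
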