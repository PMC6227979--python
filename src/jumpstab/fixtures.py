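"""Synthetic joint-kinematics fixtures emulating measured avian jumps.

Published joint-angle recordings of jumping birds are not redistributable
as data tables, so this module *generates* kinematics with the same gross
structure: a countermovement that lowers the body centre of gravity,
followed by a rapid coordinated extension of all leg joints over roughly
0.1-0.3 s, with twice-differentiable angle histories and peak body
accelerations of a few g.  Everything produced here is synthetic and is
labelled as such in the file metadata; it stands in for digitized species
data, it does not reproduce it.

Two presets are provided:

``guineafowl_like``
    A 1.42 kg ground jumper performing a near-vertical, statically balanced
    jump (vertical jumping is the classic experimental protocol for this
    species).  The countermovement keeps the downward acceleration below
    1 g -- ground contact cannot pull -- and the extension peaks near 3 g.

``dove_like``
    A 0.052 kg perch jumper with a more vigorous countermovement (~1.3 g
    downward acceleration: the gripping foot can pull the body towards the
    perch, which is what makes the initial vertical reaction negative) and
    a sinusoidal wing upstroke during the extension phase.

Pose endpoints are specified as absolute segment directions (a readable way
to state a zigzag leg posture); they are converted to included joint angles
under the package's sign convention.  Phase blending uses quintic (C2)
smoothsteps, sampled at regular knots and interpolated with the same
natural cubic splines used for measured data.  An optional seed adds small
smooth per-joint jitter so that ensembles of fixtures differ realistically;
the generated kinematics are deterministic for a given seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .dynamics import SimConfig, simulate_perch
from .kinematics import JointTrajectorySet
from .morphology import MorphologyParams, WingParams, body_inertia_spheroid


class FixtureError(ValueError):
    """A fixture spec produced an invalid (e.g. self-intersecting) motion."""


@dataclass
class Pose:
    """Leg posture as absolute segment directions plus body pitch (degrees)."""

    alpha_tmt: float
    alpha_tib: float
    alpha_fem: float
    pitch: float

    def joint_angles_deg(self) -> np.ndarray:
        """Included joint angles (hip, knee, ankle, tmt) for a flat foot (phi_f = 0)."""
        q_tmt = self.alpha_tmt
        q_ankle = self.alpha_tib - self.alpha_tmt - 180.0
        q_knee = self.alpha_fem - self.alpha_tib - 180.0
        q_hip = self.pitch - self.alpha_fem - 180.0
        return np.array([q_hip, q_knee, q_ankle, q_tmt])


@dataclass
class FixtureSpec:
    """Specification of a synthetic jumping fixture."""

    preset: str
    morphology: MorphologyParams
    stand: Pose
    crouch: Pose
    extended: Pose
    t_hold: float = 0.05
    t_countermove: float = 0.20
    t_extend: float = 0.15
    t_tail: float = 0.05
    crouch_depth: float = 1.0
    joint_offsets: dict = field(default_factory=dict)  # per-joint extension timing offset (s)
    knot_dt: float = 0.0075
    seed: int | None = None
    jitter_deg: float = 0.3
    accel_band_g: tuple[float, float] = (2.0, 6.0)
    wing: WingParams | None = None

    @property
    def duration(self) -> float:
        return self.t_hold + self.t_countermove + self.t_extend + self.t_tail


def _quintic(u: float) -> float:
    if u <= 0.0:
        return 0.0
    if u >= 1.0:
        return 1.0
    return u * u * u * (10.0 + u * (-15.0 + 6.0 * u))


_JOINTS = ("hip", "knee", "ankle", "tmt")


def _presets() -> dict[str, FixtureSpec]:
    gf_morph = MorphologyParams(
        body_mass=1.42,
        body_inertia=body_inertia_spheroid(1.42, math.pi * 0.055**2, 2.0),
        l_foot=0.06, l_tmt=0.08, l_tibiotarsus=0.12, l_femur=0.07,
    )
    gf = FixtureSpec(
        preset="guineafowl_like",
        morphology=gf_morph,
        stand=Pose(102.0, 44.0, 125.0, 5.0),
        crouch=Pose(100.0, 20.0, 165.0, 5.0),
        extended=Pose(95.0, 62.0, 105.0, 15.0),
        t_hold=0.05, t_countermove=0.25, t_extend=0.14, t_tail=0.06,
    )
    dove_morph = MorphologyParams(
        body_mass=0.052,
        body_inertia=body_inertia_spheroid(0.052, math.pi * 0.015**2, 2.0),
        l_foot=0.015, l_tmt=0.021, l_tibiotarsus=0.030, l_femur=0.018,
    )
    dove = FixtureSpec(
        preset="dove_like",
        morphology=dove_morph,
        stand=Pose(102.0, 44.0, 125.0, 5.0),
        crouch=Pose(100.0, 20.0, 165.0, 5.0),
        extended=Pose(96.0, 64.0, 102.0, 25.0),
        t_hold=0.02, t_countermove=0.095, t_extend=0.075, t_tail=0.03,
        wing=WingParams(
            wing_total_mass=0.008,
            segment_lengths=(0.030, 0.035, 0.040),
            upstroke_period=0.075,
            start_time=0.115,  # upstroke spans the extension phase
        ),
    )
    return {"guineafowl_like": gf, "dove_like": dove}


PRESET_NAMES = tuple(_presets())


def fixture_spec(preset: str, **overrides) -> FixtureSpec:
    """Return a (possibly modified) copy of a named preset spec."""
    presets = _presets()
    if preset not in presets:
        raise KeyError(f"unknown preset {preset!r}; choose from {sorted(presets)}")
    return replace(presets[preset], **overrides)


@dataclass
class GeneratedFixture:
    morph: MorphologyParams
    traj: JointTrajectorySet
    wing: WingParams | None
    spec: FixtureSpec
    meta: dict


def generate_fixture(spec: FixtureSpec | str, validate: bool = True) -> GeneratedFixture:
    """Generate the morphology and joint trajectories of a synthetic jump.

    The motion holds the stand pose, blends to the crouch (scaled by
    ``crouch_depth``), then extends to the final pose, each with a quintic
    smoothstep; per-joint timing offsets shift individual extension ramps.
    Validation runs the kinematics through the perch model and asserts that
    the peak body acceleration lies in ``accel_band_g`` and that the CoG
    height has exactly one interior minimum (the crouch); a chain passing
    below the ground plane is rejected as self-intersecting.
    """
    if isinstance(spec, str):
        spec = fixture_spec(spec)

    q_stand = spec.stand.joint_angles_deg()
    q_crouch_full = spec.crouch.joint_angles_deg()
    q_crouch = q_stand + spec.crouch_depth * (q_crouch_full - q_stand)
    q_ext = spec.extended.joint_angles_deg()

    t0_cm = spec.t_hold
    t1_cm = spec.t_hold + spec.t_countermove
    t1_ext = t1_cm + spec.t_extend
    T = spec.duration
    offsets = np.array([float(spec.joint_offsets.get(j, 0.0)) for j in _JOINTS])

    def angles_at(t: float) -> np.ndarray:
        s_cm = _quintic((t - t0_cm) / spec.t_countermove)
        q = q_stand + s_cm * (q_crouch - q_stand)
        s_ext = np.array([_quintic((t - t1_cm - off) / spec.t_extend) for off in offsets])
        return q + s_ext * (q_ext - q_crouch)

    n_knots = int(round(T / spec.knot_dt)) + 1
    times = np.linspace(0.0, T, n_knots)
    angles = np.array([angles_at(t) for t in times])

    meta_jitter = {}
    if spec.seed is not None and spec.jitter_deg > 0:
        rng = np.random.default_rng(spec.seed)
        for j in range(4):
            amp = spec.jitter_deg * rng.uniform(0.5, 1.0)
            freq = rng.uniform(1.0, 3.0) / T
            phase = rng.uniform(0.0, 2.0 * math.pi)
            angles[:, j] += amp * np.sin(math.pi * times / T) * np.sin(
                2.0 * math.pi * freq * times + phase)
            meta_jitter[_JOINTS[j]] = {"amp_deg": amp, "freq_hz": freq, "phase": phase}

    traj = JointTrajectorySet.from_degrees(times, angles)
    meta = {
        "synthetic": True,
        "preset": spec.preset,
        "seed": spec.seed,
        "jitter": meta_jitter,
        "duration_s": T,
        "phases": {"hold": [0.0, t0_cm], "countermovement": [t0_cm, t1_cm],
                   "extension": [t1_cm, t1_ext], "tail": [t1_ext, T]},
    }
    fixture = GeneratedFixture(spec.morphology, traj, spec.wing, spec, meta)
    if validate:
        _validate(fixture)
    return fixture


def _validate(fx: GeneratedFixture) -> None:
    res = simulate_perch(fx.morph, fx.traj, SimConfig(output_dt=1e-3))
    g = fx.morph.g
    acc = np.hypot(res.ax_B, res.ay_B)
    peak_g = float(acc.max()) / g
    lo, hi = fx.spec.accel_band_g
    if not (lo <= peak_g <= hi):
        raise FixtureError(
            f"peak body acceleration {peak_g:.2f} g outside the configured band "
            f"[{lo}, {hi}] g; adjust pose endpoints or phase durations")
    y = res.y_B
    # exactly one prominent interior minimum (the crouch); jitter-scale
    # wiggles (< 2% of the total height excursion) do not count
    from scipy.signal import find_peaks

    minima, _ = find_peaks(-y, prominence=0.02 * float(np.ptp(y)))
    distinct = int(minima.size)
    if distinct != 1:
        raise FixtureError(
            f"CoG height must have exactly one interior minimum (the crouch); found {distinct}")
    if float(res.y_B.min()) < 0.0:
        raise FixtureError("chain passes below the ground plane (self-intersecting fixture)")
    fx.meta.update({"peak_accel_g": peak_g,
                    "crouch_time_s": float(res.t[int(np.argmin(y))])})


def write_fixture(fixture: GeneratedFixture, out_dir, stem: str | None = None) -> dict[str, Path]:
    """Write the trajectory CSV, morphology config and metadata of a fixture."""
    from .io import write_morphology, write_trajectory

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = stem or fixture.spec.preset
    paths = {
        "trajectory": out / f"{stem}_trajectory.csv",
        "morphology": out / f"{stem}_morphology.json",
        "meta": out / f"{stem}_meta.json",
    }
    write_trajectory(fixture.traj, paths["trajectory"])
    write_morphology(fixture.morph, paths["morphology"])
    meta = dict(fixture.meta)
    if fixture.wing is not None:
        meta["wing"] = fixture.wing.to_config()
    paths["meta"].write_text(json.dumps(meta, indent=2) + "\n")
    return paths
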