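# Methods

## Model overview and assumptions

The jumper is planar: both legs act as a single chain in the sagittal
(x–y) plane, with x forward, y up and angles anticlockwise-positive. The
chain is foot (rigid toe segment spanning the rear and front contact
points) — tarsometatarsus — tibiotarsus — femur — body, joined by revolute
joints at the TMT, ankle, knee and hip. All mass and pitch inertia sit in
the body (legs massless); the body inertia may be supplied directly or
derived from a uniform prolate-spheroid trunk, `I = m(a² + b²)/5` with
semi-minor axis `b = sqrt(area/π)` and semi-major `a = slenderness·b`.
The trunk cross-section area and any wing mass are configuration inputs
(in the literature they typically come from allometric regressions, which
are not bundled here).

Joint motion is *prescribed*: the model asks what reactions and body motion
a given set of joint-angle time histories produces, not what torques
produce them. Trajectories are natural cubic splines (zero second
derivative at the end knots) through knot samples, so angle, rate and
acceleration are continuous; degrees in all files, radians internally.

Included joint angles are measured anticlockwise from the distal to the
proximal segment; a straight (colinear) joint is π. With a flat foot, a
vertical leg has `q_tmt = q_hip = 90°`, `q_ankle = q_knee = 180°`, and the
body pitch is `φ_B = φ_f + Σq + 3π (mod 2π)`.

## Stability analytics

The acceleration angle is computed as `θ = atan2(ÿ_B + g, ẍ_B)`, i.e. the
elevation of the net ground reaction `m(ẍ_B, ÿ_B + g)`; static stance gives
θ = 90°, and freefall (zero reaction) has no angle and raises an error.
The CoP is `x_P = x_B − y_B·cot θ + T_B/(‖R_P‖ sin θ)`; the cotangent form
is forced by the θ = 90° limit (a vertical reaction must pass through the
CoG). All stability queries treat `‖R_P‖ → 0` as an error rather than
returning infinities.

Stability windows (the set of θ with `0 ≤ x_P(θ) ≤ x_C`) are found by
0.1°-grid sampling plus bisection to 1e-9 rad, because the torque term
makes the boundary transcendental in θ; for zero torque the closed form
`[arccot(x_B/y_B), arccot((x_B − x_C)/y_B)]` is recovered and used as a
test oracle. For extreme torques the admissible set can in principle be
disconnected; the longest contiguous sector is returned. A point contact
(`x_C = 0`) degenerates to a single admissible direction.

The spring-leg model uses the closed-form harmonic solution about the
equilibrium compression `mg/k`; toe-off (spring at natural length)
requires `k·d > 2mg` — an initial compression below that leaves the body
oscillating without ever unloading the spring, and is flagged as
no-toe-off. Peak body speed occurs at the equilibrium crossing, strictly
before toe-off.

The 1-D toe-off simulator marches the leg-length profile at a fixed step
(default 10 µs), refines toe-off instants (`L̈ = −g` crossings, or a
declared lock) by bisection, propagates flight ballistically in closed
form, and lets contact resume when the ballistic height falls back to the
leg length; the landing resets the body velocity to the leg rate — the
massless-leg idealisation of an inelastic touchdown. A 1e-10 m guard keeps
round-off grazing right after toe-off from registering as contact.

## Ground model

With massless legs and prescribed joints, the system has three degrees of
freedom. The whole-system Newton–Euler equations are

    m·r̈_B = R_A + R_C + (0, −m g) + F_wing
    I_B·ω̇_B = Σ (r_i − r_B) × F_i + T_wing

with contact forces depending on positions and velocities only, so the ODE
is explicit. The integrator carries the *body* pose and rates as state and
recovers the foot pose algebraically from the chain map at every
evaluation; this is the same 3-DoF reduction as integrating foot-pose
coordinates, but it makes the flight phase exactly ballistic (RK4
reproduces constant acceleration without re-integrating the prescribed
joint terms), which is what the post-toe-off invariants (parabolic CoG
path, constant pitch rate, both to 1e-9) require. Stutters need no special
handling: a premature toe-off simply removes the contact forces, and
contact resumes if the foot comes back down.

Integration is fixed-step RK4, default `dt = 1e-5 s`, with contact
activation evaluated at every substep and no event localisation; the
high-frequency rocking this can produce on stiff ground is a property of
the rigid-foot model, not a numerical artefact. Events (toe-off times) are
refined below the output sampling interval by interpolating the smoothly
decaying normal force.

**Stability limit.** The contact dampers make the explicit scheme
conditionally stable. The dominant eigenvalue is the tangential damper
acting through the body-height lever on the pitch inertia,
`λ ≈ 2c_t(h²/I_B + 1/m) + 2c_n/m` with `h` the CoG height. `simulate_ground`
evaluates this at the initial pose and refuses to start if `λ·dt` exceeds
the RK4 real-axis limit (2.78), with a suggested step in the message. At
guinea-fowl scale the nominal 10 µs step has `λ·dt ≈ 0.25`; a dove-scale
*ground* model (tiny pitch inertia) needs `dt ≲ 5e-6 s`. Runtime guards
additionally abort on non-finite or wildly diverging states.

## Contact model

Each toe node carries a unilateral spring-damper normal contact:
`F = max(0, k·δ + c·δ̇)` while penetrating (δ > 0), zero otherwise, with
`c = 2ζ√(k·m)` and ζ = 1 (critical damping against the total system mass,
the only inertia in the model). Stiffness presets: soft 2 kN/m, firm
40 kN/m, hard 80 kN/m. Horizontal load transfer is an overdamped bilateral
damper `F_x = −c_t·ẋ` (default `c_t = 1e3 N·s/m`), active only while the
node carries positive normal load — friction without normal force would
drag the foot during the unloading tail and break the ballistic-flight
invariants. This is not a Coulomb model; it admits a small lateral drift,
which is one of the quantities the verification suite bounds (< 1% of toe
length at the nominal damping). The reported CoP is the normal-force-
weighted mean of the loaded node positions, defined only while the total
normal load is positive.

## Perch model

The gripping foot is assumed to prevent both slipping and rotation about
the perch, so the foot pose is fixed and the body motion follows from the
joint trajectories alone. Reactions come from inverse dynamics about the
perch point (taken at the TMT joint, i.e. the rear-toe node):
`R_P = m(r̈_B + g ĵ) − F_wing` and
`T_grip = I_B ω̇_B + (r_B − r_P) × (m r̈_B − F_grav − F_wing) − T_wing`,
reported normalized by `m·g·L_max` with `L_max` the sum of the four leg
segment lengths. The model has no toe-off; the *toe-disengagement* instant
used for summary metrics is, by default, the first time after the peak
vertical reaction that it falls back through body weight (overridable).
At that instant the *stable-angle extension* is the angle between the net
reaction direction and the zero-torque stability direction (the line from
the perch point through the CoG) — the widening of the admissible jump-
angle range purchased by the grip torque.

## Wing inertial loads

The wing pair is reduced to three point masses per side at the segment
centres, following a C² smoothstep in both elevation and extension over
one upstroke period (initially fully flexed, fully extended at the end of
the upstroke), after which the pose holds. Lateral components cancel by
left/right symmetry; the net sagittal force and shoulder pitch torque are
closed-form second derivatives of the mass positions. Accelerations are
taken relative to the shoulder (the shoulder's own acceleration is not fed
back), and wing weight is included in the load term so the body equations
use body mass only. Aerodynamics is out of scope; an
`external_force(t, state)` hook on `SimConfig` is the extension point.

## Events and metrics

Force thresholds default to `tol_force = 1e-3·m·g` — well below dynamic
force scales, well above integration chatter — with a 1 ms debounce.
Crouch is the (earliest) CoG minimum before final toe-off; final toe-off
is the first time after which both normal forces stay below tolerance;
rear toe-off the last downward crossing of the rear normal force before
it; stutters are debounced intervals with both normals unloaded that end
with contact regained; tipping onset requires single-node contact
persisting beyond the debounce with growing foot-rotation rate (to
distinguish tipping from rocking). Perch runs report only the crouch (the
grip never releases). Normalized outputs use the *simulated* toe-off time
(the experimental, video-based definition has no model counterpart; the
choice is recorded in the run metadata).

`perturb_trajectory` scales one joint's angular rate inside a time window
with C¹ smoothstep blending at the edges. The angle is continuous and
equals the input before the window; after it, the accumulated offset of
the scaled rate remains — modified kinematics legitimately change the
subsequent motion, and an exact return to the original angles would
contradict a uniformly scaled rate.

## Synthetic fixtures

Published joint-angle recordings of jumping birds are digitized from video
in the primary literature and are not redistributable, so the fixture
generator *emulates* their structure: hold — countermovement — rapid
coordinated extension — hold, with quintic (C²) phase blending sampled at
~7.5 ms knots and re-interpolated by the same natural splines used for
file input. Pose endpoints are stated as absolute segment directions
(a readable zigzag parameterisation) and converted to included joint
angles. The generator validates every fixture by running it through the
perch model: peak body acceleration must fall in a configured band
(default 2–6 g, matching reported take-off accelerations for these
species' size range) and the CoG height must have exactly one prominent
interior minimum (the crouch); a chain reaching below the ground plane is
rejected.

The guinea-fowl-like preset (1.42 kg; segment lengths 0.06/0.08/0.12/0.07 m,
`L_max = 0.33 m`) performs a near-vertical, statically balanced jump —
vertical jumping is the classic experimental protocol for the species. Its
countermovement keeps the downward acceleration below 1 g because ground
contact cannot pull, and the extension peaks near 4.4 g; the CoG tracks the
mid-foot so the stance is balanced on both soft and firm ground. The
dove-like preset (0.052 kg, `L_max = 0.084 m`) is a perch jumper: its
countermovement deliberately exceeds 1 g downward (~1.3 g), which is only
possible because the gripping foot can pull — this is what makes the early
vertical reaction negative — and its wing upstroke spans the extension
phase. An optional integer seed adds small (≈0.3°) smooth sinusoidal
jitter per joint; generation is deterministic for a given seed.

What the fixtures do *not* emulate: measured inter-joint timing offsets
(supported but zero by default), joint compliance, foot flexibility, and
species-specific pitch strategies. Passing tests on these fixtures
therefore validates the mechanics and the numerics, not any particular
bird's kinematics; the headline magnitudes reported for real birds
(normalized grip torque, grip-enabled widening of stable angles, wing
contribution) appear here as qualitative signatures with the right sign
and order of magnitude only.

## Verification problem sizes

The verification suite runs the guinea-fowl-like fixture (0.5 s of motion,
50 000 steps at 10 µs; 100 000 at the halved step) for the convergence,
drift and stiffness-robustness checks; the property oracles use 10⁴ random
states for the CoP moment balance and the window/bounds duality, and a
0.02 s segment at 0.5 µs for the penalty-formulation cross-check, where the
body is simulated as a free rigid body coupled to a near-massless foot by
stiff joint-following penalties (penalty stiffness 1e7 N/m; foot inertia
2e-5 kg·m², the smallest value for which the explicit oracle itself is
stable, contributing ≈0.5% bias — below the 1% comparison tolerance).

## Known limitations

Planar only; two contact nodes on a rigid toe (no interphalangeal
flexibility); viscous rather than Coulomb friction; no joint or tendon
compliance, which is why stiff-ground simulations rock and stutter more
than real birds do; no muscle force/power limits (kinematically driven);
no aerodynamics; wing loads ignore shoulder acceleration feedback. The
explicit fixed-step integrator requires respecting the documented
stability limit for light, low-inertia morphologies.
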