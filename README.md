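# jumpstab

Dynamics and tipping-stability analysis of jumping take-off, written for
biomechanists and bio-roboticists studying how a jumper — an avian one in
particular — keeps control of its body attitude and trajectory during the
explosive acceleration from crouch to lift-off.

A jump fails in two characteristic ways well before muscle strength is the
limit. First, *premature toe-off*: for a body of mass `m` on a (nearly)
massless leg the ground reaction is `R = m(g + ÿ_B)`, so contact is lost the
instant the upward acceleration falls to `−g` — while the leg is still
extending. Second, *tipping*: the centre of pressure (CoP, equivalent to the
zero-moment point) must stay between the rear and front toe, which for a
planar jumper puts hard bounds on where the centre of gravity (CoG) may be.
Writing `θ` for the elevation of the net ground reaction (the *acceleration
angle*), `T_B` for the applied pitch torque and `x_C` for the foot length,
the CoP sits at

```
x_P = x_B − y_B·cot θ + T_B / (‖R_P‖·sin θ)
```

and demanding `0 ≤ x_P ≤ x_C` yields dimensionless fore/aft CoG bounds

```
x'_aft = y'_B / tan θ − T'_B / sin θ,      x'_fore = x'_aft + 1
```

with `y'_B = y_B/x_C` and `T'_B = T_B/(‖R_P‖·x_C)` — or, dually, an angular
*stability window* of reaction directions for a given CoG. For `y' = 1` and
no torque the bounds coincide with the foot at θ = 90° and reach the front
toe at exactly 45°: shallower jumps need the CoG ahead of the foot, or a
nose-up torque to pull the admissible range back.

The package implements:

* **Analytical models** (`jumpstab.stability`): 1-D toe-off with stutter
  (intermittent contact) detection, the closed-form spring-leg jumper, the
  acceleration angle, CoP location, CoG bounds, stability windows and
  stability maps.
* **A planar multibody simulator** (`jumpstab.dynamics`): a rigid
  foot–tarsometatarsus–tibiotarsus–femur–body chain with massless legs and
  *prescribed* joint-angle time histories (cubic splines through knot
  samples). The ground model integrates the three floating degrees of
  freedom with unilateral, critically damped normal contacts and tangential
  dampers at the rear/front toe nodes (fixed-step RK4, 10 µs default); the
  perch model fixes the gripping foot and recovers the required reaction
  force and grip torque by inverse dynamics. Optional wing inertial loads
  use a sinusoidal three-segment wing-pair model.
* **Event detection and metrics** (`jumpstab.events`): crouch, rear toe-off,
  stutters, tipping onset, final toe-off; take-off speed/angle, impulses,
  normalized forces `F/(m g)` and grip torque `T/(m g L_max)`.
* **Synthetic fixtures** (`jumpstab.fixtures`): generated countermovement-
  and-extension kinematics at guinea-fowl (1.42 kg, ground) and diamond-dove
  (52 g, perch) scale, standing in for digitized experimental recordings
  that are not redistributable.

## Worked example

```sh
python examples/ground_takeoff.py
```

```
fixture: m = 1.42 kg, L_max = 0.330 m, peak accel 4.43 g
  event crouch         t = 0.2927 s
  event tipping_onset  t = 0.2956 s
  event final_toe_off  t = 0.3659 s
  event rear_toe_off   t = 0.3659 s
take-off speed 1.687 m/s at 90.4 deg (near-vertical jump), pitch rate 2.42 rad/s
peak vertical force 5.56 body weights
```

The crouch (CoG minimum) ends the countermovement at 0.293 s; the following
extension accelerates the body at up to ~4.4 g, a brief rocking episode puts
the system on a single toe node (`tipping_onset`), and final toe-off occurs
at 0.366 s — while the leg is still extending, because the vertical
deceleration has reached −g. The other example scripts cover the stability
map and windows (`stability_map.py`), 1-D toe-off and the spring leg
(`one_d_toe_off.py`), perch take-off with grip torque and wing effects
(`perch_takeoff.py`), and toe-off modulation through the TMT joint rate
(`tmt_modulation.py`). A thin CLI exposes the same operations
(`jumpstab --help`: `simulate-ground`, `simulate-perch`, `stability-map`,
`events`, `make-fixture`, `sensitivity`).

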