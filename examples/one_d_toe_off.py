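"""One-dimensional toe-off: when does the foot leave the ground?

For a body on a massless extensible leg, contact is lost exactly when the
leg deceleration reaches -g (the reaction R = m(g + y'') hits zero), not
when the leg reaches full extension.  A spring leg shows the same thing in
closed form: body speed peaks *before* toe-off.
"""

import numpy as np

import jumpstab as js
from jumpstab.stability import LegExtensionProfile

# an extension with a mid-course dip in acceleration below -g: the jumper
# leaves the ground early, falls back on (a "stutter"), and takes off again
t = np.linspace(0, 0.4, 81)
L = 0.2 + 0.35 * t - 0.02 * np.sin(2 * np.pi * t / 0.16)
res = js.simulate_1d(LegExtensionProfile.from_spline(t, L), m=1.0, dt=1e-5)
print(f"toe-off events at t = {[f'{x:.4f}' for x in res.toe_off_times]} s")
print(f"contact regained at t = {[f'{x:.4f}' for x in res.touchdown_times]} s")
print(f"distinct contact intervals: {res.n_contact_intervals} "
      "(more than one = the jump stutters)")

spring = js.spring_leg_takeoff(m=1.0, k=100.0, d=0.5)
print(f"\nspring leg (k=100 N/m, compressed 0.5 m):")
print(f"  peak body speed {spring.peak_speed:.3f} m/s at t = {spring.peak_speed_time:.4f} s")
print(f"  toe-off   speed {spring.toe_off_speed:.3f} m/s at t = {spring.toe_off_time:.4f} s")
print("  the body is already decelerating when the spring reaches natural length")
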