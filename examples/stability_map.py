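"""Tipping-stability margins: where may the centre of gravity sit?

Builds the dimensionless stability map: for each acceleration angle theta
(elevation of the net ground reaction) and applied-torque level T', the
fore/aft bounds on the CoG position, in units of foot length, that keep the
centre of pressure within the foot.
"""

import numpy as np

import jumpstab as js

grid = js.stability_map(theta_deg=np.arange(15.0, 91.0, 15.0),
                        torque_levels=[-0.3, 0.0, 0.3], y_prime=1.0)
print(grid.table.to_string(index=False, float_format=lambda v: f"{v:7.3f}"))

print("""
Each row: the CoG must lie between x_aft and x_fore (rear toe = 0, front
toe = 1) or the bird tips. At theta = 90 deg (vertical push) the zero-torque
range is exactly the foot; at 45 deg it already starts at the front toe, so
shallower jumps need the CoG beyond the foot or a nose-up torque (T' > 0),
which shifts the admissible range aft.""")

window = js.stability_window(x_B=0.5, y_B=1.0, x_C=1.0, T_B=0.0, R_mag=10.0)
print(f"Dual view -- admissible reaction directions for a CoG at mid-foot: "
      f"[{np.degrees(window.theta_lo):.2f}, {np.degrees(window.theta_hi):.2f}] deg")
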