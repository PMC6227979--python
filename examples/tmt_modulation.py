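"""Modulating toe-off with the TMT joint.

Toe-off is governed by the vertical acceleration falling to -g, so speeding
up the distal (tarsometatarsal) joint during the final extension sustains
the acceleration longer and *delays* toe-off -- a candidate low-level
control handle for jumping animals and robots.
"""

import jumpstab as js

fx = js.generate_fixture(js.fixture_spec("guineafowl_like", seed=1))
cfg = js.SimConfig(dt=2e-5)

base = js.simulate_ground(fx.morph, fx.traj, cfg)
t0 = js.final_toe_off_time(base)
print(f"baseline toe-off: t = {t0:.4f} s")

for scale in (1.1, 1.2):
    faster = js.perturb_trajectory(fx.traj, "tmt", scale, window=(0.30, 0.46))
    res = js.simulate_ground(fx.morph, faster, cfg)
    t1 = js.final_toe_off_time(res)
    print(f"TMT rate x {scale:.1f}:  toe-off t = {t1:.4f} s "
          f"(delayed by {1e3 * (t1 - t0):+.2f} ms)")
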