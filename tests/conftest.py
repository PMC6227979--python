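"""Shared fixtures.

The paired dt / stiffness ground runs are expensive (tens of seconds), so
they are session-scoped and shared between the dynamics tests and the
model-verification (acceptance) tests.
"""

import pytest

import jumpstab as js


@pytest.fixture(scope="session")
def gf_fixture():
    """Guinea-fowl-like synthetic ground-jump fixture (seed 1)."""
    return js.generate_fixture(js.fixture_spec("guineafowl_like", seed=1))


@pytest.fixture(scope="session")
def dove_fixture():
    """Dove-like synthetic perch-jump fixture (seed 1)."""
    return js.generate_fixture(js.fixture_spec("dove_like", seed=1))


@pytest.fixture(scope="session")
def firm_run(gf_fixture):
    cfg = js.SimConfig(dt=1e-5, contact=js.ContactParams(stiffness="firm"))
    return js.simulate_ground(gf_fixture.morph, gf_fixture.traj, cfg)


@pytest.fixture(scope="session")
def half_dt_run(gf_fixture):
    cfg = js.SimConfig(dt=5e-6, contact=js.ContactParams(stiffness="firm"))
    return js.simulate_ground(gf_fixture.morph, gf_fixture.traj, cfg)


@pytest.fixture(scope="session")
def soft_run(gf_fixture):
    cfg = js.SimConfig(dt=1e-5, contact=js.ContactParams(stiffness="soft"))
    return js.simulate_ground(gf_fixture.morph, gf_fixture.traj, cfg)


@pytest.fixture(scope="session")
def dove_perch_run(dove_fixture):
    cfg = js.SimConfig(output_dt=5e-4)
    return js.simulate_perch(dove_fixture.morph, dove_fixture.traj, cfg)
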