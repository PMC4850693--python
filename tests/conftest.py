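import numpy as np
import pytest

import wavearc as w
from wavearc.fixtures import FixtureSpec, generate_plan


@pytest.fixture(scope="session")
def rules():
    return w.TrajectoryRules()


@pytest.fixture(scope="session")
def mc():
    return w.MachineConstraints()


@pytest.fixture(scope="session")
def wave_trajectory():
    """Two-sub-arc wave with a ring direction reversal at the middle MP."""
    return w.WaveArcTrajectory([
        w.AngularPosition(0, 0),
        w.AngularPosition(24, 10),
        w.AngularPosition(52, -14),
    ])


def make_coplanar_plan(gantry_span=180.0, total_mu=300.0):
    """Single coplanar arc with constant MU per CP."""
    traj = w.WaveArcTrajectory([w.AngularPosition(0, 0),
                                w.AngularPosition(gantry_span, 0)])
    beams = w.discretize_beams(traj)
    cps, norms = w.build_control_points(beams)
    wt = total_mu / (len(cps) - 1)
    plan = w.DeliveryPlan(
        traj,
        tuple(w.ControlPoint(p, 0.0 if i == 0 else wt)
              for i, p in enumerate(cps)),
        cp_norms=norms)
    return plan


def make_plan_from_trajectory(traj, total_mu=300.0):
    beams = w.discretize_beams(traj)
    cps, norms = w.build_control_points(beams)
    wt = total_mu / (len(cps) - 1)
    return w.DeliveryPlan(
        traj,
        tuple(w.ControlPoint(p, 0.0 if i == 0 else wt)
              for i, p in enumerate(cps)),
        cp_norms=norms)


@pytest.fixture(scope="session")
def coplanar_plan():
    return make_coplanar_plan()


@pytest.fixture(scope="session")
def fixture_plan():
    return generate_plan(FixtureSpec(seed=7))


def rect_aperture(n=10, left=-3.0, right=3.0, width=0.5):
    return w.MLCAperture(np.full(n, left), np.full(n, right), np.full(n, width))
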