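import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import jawstatics as js

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def planar_toy_path():
    from importlib import resources

    with resources.as_file(
        resources.files("jawstatics").joinpath("data/planar_toy.json")
    ) as p:
        yield p


@pytest.fixture(scope="session")
def planar_toy(planar_toy_path):
    return js.load_jaw_model(planar_toy_path)


@pytest.fixture(scope="session")
def planar_family():
    """Planar jaw with closed-form expected forces per (bite point, gape)."""
    return js.make_planar_jaw(js.SyntheticJawParams(seed=0))


def brute_force_equilibrium(model, label, gape_deg, orientation_deg, stress=30.0):
    """Independent equilibrium oracle: assemble the full 6x6 linear system
    (3 force-balance + 3 moment-balance equations; unknowns are the bite
    magnitude, the joint force vector, and the two hinge constraint torques)
    and solve it with numpy. Returns (bite_force, joint_force)."""
    pose = js.open_jaw(model, gape_deg)
    center, axis = js.joint_axis(pose)
    e1 = np.array([1.0, 0.0, 0.0]) - np.dot([1.0, 0.0, 0.0], axis) * axis
    if np.linalg.norm(e1) < 1e-9:
        e1 = np.array([0.0, 0.0, 1.0]) - np.dot([0.0, 0.0, 1.0], axis) * axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    u = js.reaction_direction(axis, orientation_deg)
    r_bite = pose.bite_point(label).position.to_array() - center.to_array()

    A = np.zeros((6, 6))
    b = np.zeros(6)
    A[0:3, 0] = u
    A[0:3, 1:4] = np.eye(3)
    A[3:6, 0] = np.cross(r_bite, u)
    A[3:6, 4] = e1
    A[3:6, 5] = e2
    for m in pose.muscles:
        f = js.muscle_force(m, stress)
        b[0:3] -= f.vector()
        b[3:6] -= np.cross(f.application_point.to_array() - center.to_array(), f.vector())
    x = np.linalg.solve(A, b)
    return x[0], x[1:4]


@pytest.fixture(scope="session")
def equilibrium_oracle():
    return brute_force_equilibrium
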