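import numpy as np
import pytest

from neckforce.anthropometry import AnthroProfile
from neckforce.model import Body, Joint, MuscleSpec, NeckModel, build_default_model
from neckforce.muscles import REDUCED_MUSCLE_SET

_NO_MARKERS = {"TP": np.zeros(3), "LH": np.zeros(3), "RH": np.zeros(3)}


@pytest.fixture(scope="session")
def full_model():
    return build_default_model()


@pytest.fixture(scope="session")
def reduced_model():
    return build_default_model(muscle_names=REDUCED_MUSCLE_SET)


def make_pendulum(mass=6.377, com_z=0.1073, inertia=1e-4, stiffness=0.0,
                  damping=0.0, axis=(0.0, 1.0, 0.0)):
    """Single-joint inverted pendulum: the analytic reduction used by
    the inverse-dynamics and energy-conservation oracles."""
    joints = [Joint("fe", np.asarray(axis, dtype=float), np.zeros(3))]
    bodies = [Body("head", 1, mass, np.array([0.0, 0.0, com_z]),
                   np.eye(3) * inertia)]
    return NeckModel(joints, bodies, [], dict(_NO_MARKERS),
                     0.0, np.full(1, stiffness), np.full(1, damping))


def make_two_muscle_toy(arm=0.02, f_max=100.0, depths=("superficial", "superficial")):
    """1-DOF joint driven by two parallel synergists with equal moment arms."""
    joints = [Joint("fe", np.array([0.0, 1.0, 0.0]), np.zeros(3))]
    bodies = [Body("head", 1, 1.0, np.array([0.0, 0.0, 0.1]), np.eye(3) * 1e-4)]
    line = dict(origin=np.array([arm, 0.0, -0.1]), insertion=np.array([arm, 0.0, 0.1]))
    muscles = [
        MuscleSpec("a", "right", depths[0], "torso", line["origin"],
                   "head", line["insertion"], f_max, "b"),
        MuscleSpec("b", "right", depths[1], "torso", line["origin"].copy(),
                   "head", line["insertion"].copy(), f_max, "a"),
    ]
    return NeckModel(joints, bodies, muscles, dict(_NO_MARKERS),
                     0.0, np.zeros(1), np.zeros(1))


@pytest.fixture
def mean_profile():
    return AnthroProfile(6.377, 39.920, 10.730)
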