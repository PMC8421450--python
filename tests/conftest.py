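import numpy as np
import pytest

from radfit.io import FrameSchedule
from radfit.phantom import InputFunction, KineticParams, PhantomSpec, SphereSpec


@pytest.fixture(scope="session")
def sim_schedule():
    return FrameSchedule.default_simulation()


@pytest.fixture(scope="session")
def short_schedule():
    """12-frame, 20-min schedule for fast kinetic tests."""
    durations = np.concatenate([np.full(4, 30.0), np.full(8, 135.0)])
    starts = np.cumsum(durations) - durations
    return FrameSchedule(start=starts, duration=durations)


@pytest.fixture(scope="session")
def constant_input():
    """Constant arterial input Cb = 10 kBq/mL from t = 0."""
    return InputFunction(amplitudes=(10.0, 0.0, 0.0),
                         decay_rates=(0.0, 0.0, 0.0), delay=0.0)


@pytest.fixture()
def tiny_phantom_spec():
    """Small three-sphere phantom for fast end-to-end runs."""
    spheres = [
        SphereSpec(center=(9, 9, 4), diameter_mm=10.0, preset="low"),
        SphereSpec(center=(27, 9, 4), diameter_mm=10.0, preset="medium"),
        SphereSpec(center=(18, 27, 4), diameter_mm=10.0, preset="high"),
    ]
    return PhantomSpec(grid_shape=(36, 36, 9), spacing_mm=2.0,
                       spheres=spheres, blood_box=((2, 34), (32, 35), (2, 7)))
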