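import numpy as np
import pytest

from capstrack.cleanliness import default_model
from capstrack.geometry import CameraGeometry


@pytest.fixture(scope="session")
def geometry():
    return CameraGeometry()


@pytest.fixture(scope="session")
def clean_model():
    return default_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def rendered_video():
    """Small rendered video with its ground truth, shared across tests."""
    from capstrack.simulator import (
        TrajectoryConfig,
        render_frames,
        simulate_trajectory,
    )

    traj = simulate_trajectory(
        TrajectoryConfig(n_frames=10, dirt_fraction=0.2, tilt_prob=0.0),
        np.random.default_rng(7),
    )
    frames = render_frames(traj, rng=np.random.default_rng(8))
    return traj, frames
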