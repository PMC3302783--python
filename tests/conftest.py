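import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from ionsite import (  # noqa: E402
    AtomID,
    Frame,
    Trajectory,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_static_trajectory(positions, n_frames=5, atoms=None):
    """Trajectory with every frame identical to `positions` (n_atoms, 3)."""
    positions = np.asarray(positions, dtype=float)
    if atoms is None:
        atoms = tuple(
            AtomID("A", "GLY", i + 1, "CA") for i in range(positions.shape[0])
        )
    frames = [Frame(positions.copy(), atoms) for _ in range(n_frames)]
    return Trajectory(frames)


@pytest.fixture
def static_pair_traj():
    """Two atoms at (0,0,0) and (3,4,0): a 3-4-5 triangle, distance 5."""
    return make_static_trajectory([[0.0, 0.0, 0.0], [3.0, 4.0, 0.0]])


def random_rotation(rng):
    """A uniformly random proper rotation matrix (QR-based)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
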