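import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")

from guidedev.geometry import Implant, RigidTransform


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish random proper rotation via QR with sign fix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def random_transform(rng: np.random.Generator, max_translation: float = 20.0) -> RigidTransform:
    return RigidTransform(random_rotation(rng), rng.uniform(-max_translation, max_translation, 3))


def random_implant(rng: np.random.Generator, length: float = 10.0) -> Implant:
    platform = rng.uniform(-30, 30, 3)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    return Implant(platform=platform, apex=platform + length * axis)


def rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    a = np.radians(angle_deg)
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
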