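import numpy as np
import pytest
import trimesh

from ergoseat.types import LandmarkSet, PointCloud


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_torso(subdivisions: int = 3) -> PointCloud:
    """Synthetic torso-like template: an icosphere stretched to trunk
    proportions (mm). Deterministic."""
    sphere = trimesh.creation.icosphere(subdivisions=subdivisions)
    pts = np.asarray(sphere.vertices) * np.array([150.0, 110.0, 300.0])
    return PointCloud(pts, np.asarray(sphere.faces))


def make_torso_landmarks(cloud: PointCloud, n: int = 24) -> LandmarkSet:
    """Well-spread landmarks via deterministic farthest-point sampling."""
    pts = cloud.points
    idx = [0]
    d = np.linalg.norm(pts - pts[0], axis=1)
    for _ in range(n - 1):
        nxt = int(np.argmax(d))
        idx.append(nxt)
        d = np.minimum(d, np.linalg.norm(pts - pts[nxt], axis=1))
    return LandmarkSet(tuple(f"lm{i}" for i in range(n)), pts[idx])


@pytest.fixture
def torso() -> PointCloud:
    return make_torso()


@pytest.fixture
def torso_landmarks(torso) -> LandmarkSet:
    return make_torso_landmarks(torso)


def random_pressure_grid(rng: np.random.Generator, max_shape=(20, 20)) -> np.ndarray:
    rows = int(rng.integers(2, max_shape[0] + 1))
    cols = int(rng.integers(2, max_shape[1] + 1))
    grid = rng.uniform(0.0, 12.0, (rows, cols))
    grid[rng.random((rows, cols)) < 0.3] = 0.0  # no-contact cells
    return grid


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, -1] *= -1
    return q
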