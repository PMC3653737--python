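import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from contourbench import AnatomyConfig, Contour, Structure, make_reference_anatomy

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

UNIT_SQUARE = np.array([(0.0, 0.0), (1.0, 0.0), (1.0, 1.0), (0.0, 1.0)])


def regular_polygon(n: int, r: float = 1.0, centre=(0.0, 0.0)) -> np.ndarray:
    th = np.arange(n) / n * 2 * np.pi
    return np.column_stack([centre[0] + r * np.cos(th), centre[1] + r * np.sin(th)])


def random_convex_polygon(rng: np.random.Generator, r_max: float = 1.5) -> np.ndarray:
    """Random convex polygon: convex hull of 8-20 points in a disc."""
    from scipy.spatial import ConvexHull

    pts = rng.uniform(-r_max, r_max, size=(rng.integers(8, 21), 2))
    hull = ConvexHull(pts)
    return pts[hull.vertices]


def cylinder_structure(radius: float, n_slices: int = 8, dz: float = 0.3,
                       n_vertices: int = 64, role: str = "other",
                       name: str = "cyl", centre=(0.0, 0.0), z0: float = 0.0) -> Structure:
    verts = regular_polygon(n_vertices, radius, centre)
    contours = [Contour(z0 + k * dz, verts, name) for k in range(n_slices)]
    return Structure(name, role, contours, dz)


@pytest.fixture(scope="session")
def reference_anatomy():
    """Small reference patient shared across tests (48 vertices/contour)."""
    return make_reference_anatomy(AnatomyConfig(), vertices_per_contour=48)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
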