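import numpy as np
import pytest

from puzzlecell import Contour, SimulationParams, fixture_shapes, generate_tissue


@pytest.fixture(scope="session")
def shapes():
    return fixture_shapes()


@pytest.fixture()
def unit_square(shapes):
    return shapes["square"]


@pytest.fixture(scope="session")
def small_tissue():
    """Tiny 3x3-ish tissue for structural and mechanical unit tests."""
    return generate_tissue(seed=3, n_cells=9, width=40.0, height=40.0, spacing=2.0)


@pytest.fixture()
def circle_contour():
    phi = np.linspace(0, 2 * np.pi, 200, endpoint=False)
    return Contour(np.column_stack([np.cos(phi), np.sin(phi)]))


def random_simple_polygon(rng: np.random.Generator, n: int = 24) -> Contour:
    """Star-shaped (hence simple) random polygon around the origin."""
    phi = np.sort(rng.uniform(0, 2 * np.pi, n))
    # enforce distinct angles
    while np.min(np.diff(phi)) < 1e-3:
        phi = np.sort(rng.uniform(0, 2 * np.pi, n))
    r = rng.uniform(0.3, 1.0, n)
    return Contour(np.column_stack([r * np.cos(phi), r * np.sin(phi)]))


@pytest.fixture(scope="session")
def default_params():
    return SimulationParams()
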