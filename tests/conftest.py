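import numpy as np
import pytest

import latgraph as lg


@pytest.fixture(scope="session")
def triangle_mesh():
    """Single equilateral triangle with unit edge length."""
    verts = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.5, np.sqrt(3) / 2, 0.0]])
    return lg.TriMesh(verts, np.array([[0, 1, 2]]))


@pytest.fixture(scope="session")
def square_mesh():
    """Unit square split into two right isoceles triangles along the diagonal."""
    verts = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [1.0, 1.0, 0.0], [0.0, 1.0, 0.0]]
    )
    return lg.TriMesh(verts, np.array([[0, 1, 2], [0, 2, 3]]))


@pytest.fixture(scope="session")
def icosahedron():
    return lg.make_mesh(lg.SyntheticSpec(subdivisions=0, radius=1.0))


@pytest.fixture(scope="session")
def small_sphere():
    """Icosphere at subdivision 2 (162 vertices) — big enough for solver tests."""
    return lg.make_mesh(lg.SyntheticSpec(subdivisions=2, radius=25.0))


@pytest.fixture(scope="session")
def focal_map(small_sphere):
    """(mesh, truth field, observations) for a smooth focal activation map."""
    spec = lg.SyntheticSpec(subdivisions=2, seed=3)
    field = lg.simulate_focal_lat(small_sphere, spec)
    obs = lg.sample_observations(small_sphere, field, 80, seed=4)
    return small_sphere, field, obs


def random_surface_graph(rng: np.random.Generator, n: int) -> lg.SurfaceGraph:
    """Random connected positively weighted graph wrapped as a SurfaceGraph."""
    edges = {(i, int(rng.integers(i))) for i in range(1, n)}  # random spanning tree
    extra = rng.integers(0, n, size=(2 * n, 2))
    for a, b in extra:
        if a != b:
            edges.add((max(a, b), min(a, b)))
    edges = np.array(sorted((min(a, b), max(a, b)) for a, b in edges))
    weights = rng.uniform(0.05, 2.0, len(edges))
    return lg.SurfaceGraph(n, edges).with_weights(weights)


def random_problem(rng: np.random.Generator, n: int):
    graph = random_surface_graph(rng, n)
    mask = rng.random(n) < rng.uniform(0.2, 0.8)
    if not mask.any():
        mask[int(rng.integers(n))] = True
    f_s = np.where(mask, rng.normal(-100.0, 40.0, n), 0.0)
    return lg.InterpolationProblem(graph, f_s, mask)
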