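"""Shared fixtures: tiny hand-built graphs and a small synthetic cohort."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp

from parcelgnn.surface import SurfaceGraph, build_graph


def graph_from_edges(edges, n: int, seed: int = 0) -> SurfaceGraph:
    """A SurfaceGraph with an explicit edge list (no meaningful faces).

    Lets tests use non-triangulated topologies (paths, stars) that cannot
    arise from a mesh; vertices get arbitrary coordinates.
    """
    rows = [e[0] for e in edges] + [e[1] for e in edges]
    cols = [e[1] for e in edges] + [e[0] for e in edges]
    adj = sp.coo_matrix(
        (np.ones(len(rows), dtype=bool), (rows, cols)), shape=(n, n)
    ).tocsr()
    adj.setdiag(False)
    adj.eliminate_zeros()
    vertices = np.random.default_rng(seed).normal(size=(n, 3))
    faces = np.zeros((1, 3), dtype=np.int64)  # placeholder, not used by graph ops
    return SurfaceGraph(vertices=vertices, faces=faces, adjacency=adj.tocsr())


def path_graph(n: int) -> SurfaceGraph:
    return graph_from_edges([(i, i + 1) for i in range(n - 1)], n)


@pytest.fixture
def triangle_graph():
    verts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
    return build_graph(verts, np.array([[0, 1, 2]]))


@pytest.fixture
def two_triangle_graph():
    verts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]])
    return build_graph(verts, np.array([[0, 1, 2], [1, 3, 2]]))


@pytest.fixture(scope="session")
def icosahedron():
    from parcelgnn.synthetic import make_mesh

    return make_mesh(0, radial_noise=0.0)


@pytest.fixture(scope="session")
def icosphere2():
    from parcelgnn.synthetic import make_mesh

    return make_mesh(2, radial_noise=0.02, seed=5)


@pytest.fixture(scope="session")
def small_cohort():
    """A fast cohort for integration-style tests (162 vertices)."""
    from parcelgnn.synthetic import SyntheticConfig, make_cohort

    cfg = SyntheticConfig(
        mesh_subdivisions=2,
        num_parcels=6,
        num_subjects=8,
        timepoints=100,
        snr=3.0,
        boundary_jitter=0,
        seed=11,
    )
    return make_cohort(cfg)
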