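"""Surface meshes as graphs: adjacency, Laplacians, spectral coordinates.

A triangulated cortical mesh induces an unweighted, undirected graph whose
vertices are mesh vertices and whose edges are triangle edges. Low-order
eigenvectors of the symmetric normalized graph Laplacian serve as
rotation/translation-invariant positional features ("spectral coordinates");
because eigenvectors are defined only up to sign and ordering, subject
coordinates are matched to a template by a Hungarian assignment on Pearson
correlation distance with per-column sign selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linear_sum_assignment

__all__ = [
    "SurfaceGraph",
    "SpectralCoordinates",
    "build_graph",
    "normalized_laplacian",
    "spectral_coordinates",
    "align_spectral",
    "geodesic_hops",
]


@dataclass(frozen=True)
class SurfaceGraph:
    """A triangulated mesh and its induced vertex-adjacency graph.

    ``adjacency`` is a symmetric boolean CSR matrix with an empty diagonal:
    two vertices are adjacent iff they share a triangle edge.
    """

    vertices: np.ndarray  # N x 3, mm
    faces: np.ndarray  # M x 3, 0-based vertex indices
    adjacency: sp.csr_matrix

    @property
    def num_vertices(self) -> int:
        return int(self.vertices.shape[0])

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(np.int64)

    def neighbors(self, v: int) -> np.ndarray:
        return self.adjacency.indices[
            self.adjacency.indptr[v] : self.adjacency.indptr[v + 1]
        ]

    def is_connected(self) -> bool:
        n_comp, _ = sp.csgraph.connected_components(self.adjacency, directed=False)
        return n_comp == 1


@dataclass(frozen=True)
class SpectralCoordinates:
    """The d Laplacian eigenvectors with smallest strictly-positive eigenvalues.

    Columns are unit-norm; eigenvalues ascending; the zero-eigenvalue
    eigenvector (carrying no positional information) is excluded.
    """

    eigenvectors: np.ndarray  # N x d
    eigenvalues: np.ndarray  # d, ascending, > 0

    @property
    def dim(self) -> int:
        return int(self.eigenvectors.shape[1])


def build_graph(vertices: np.ndarray, faces: np.ndarray) -> SurfaceGraph:
    """Build the vertex-adjacency graph of a triangulated mesh.

    Parameters
    ----------
    vertices
        ``N x 3`` array of coordinates.
    faces
        ``M x 3`` array of 0-based vertex index triples.

    Raises
    ------
    ValueError
        On out-of-range face indices, degenerate faces (repeated vertices),
        or an empty face list.
    """
    vertices = np.asarray(vertices, dtype=np.float64)
    faces = np.asarray(faces, dtype=np.int64)
    if vertices.ndim != 2 or vertices.shape[1] != 3:
        raise ValueError(f"vertices must be N x 3, got {vertices.shape}")
    if faces.ndim != 2 or faces.shape[1] != 3:
        raise ValueError(f"faces must be M x 3, got {faces.shape}")
    if faces.shape[0] == 0:
        raise ValueError("empty face list")
    n = vertices.shape[0]
    if faces.min() < 0 or faces.max() >= n:
        bad = faces[(faces < 0) | (faces >= n)]
        raise ValueError(f"face index {int(bad.flat[0])} out of range [0, {n})")
    degenerate = (
        (faces[:, 0] == faces[:, 1])
        | (faces[:, 1] == faces[:, 2])
        | (faces[:, 0] == faces[:, 2])
    )
    if degenerate.any():
        raise ValueError(f"{int(degenerate.sum())} degenerate face(s) with repeated indices")

    # Each triangle contributes its three undirected edges.
    i = np.concatenate([faces[:, 0], faces[:, 1], faces[:, 2]])
    j = np.concatenate([faces[:, 1], faces[:, 2], faces[:, 0]])
    data = np.ones(i.size, dtype=bool)
    adj = sp.coo_matrix((data, (i, j)), shape=(n, n)).tocsr()
    adj = (adj + adj.T).astype(bool)
    adj.setdiag(False)
    adj.eliminate_zeros()
    return SurfaceGraph(vertices=vertices, faces=faces, adjacency=adj.tocsr())


def normalized_laplacian(g: SurfaceGraph) -> sp.csr_matrix:
    """Symmetric normalized graph Laplacian L = I - D^{-1/2} A D^{-1/2}.

    Eigenvalues lie in [0, 2]; the smallest is 0 for a connected graph.

    Raises
    ------
    ValueError
        If any vertex is isolated (zero degree).
    """
    deg = g.degrees.astype(np.float64)
    if np.any(deg == 0):
        isolated = np.flatnonzero(deg == 0)
        raise ValueError(f"isolated vertex (zero degree): {isolated[:5].tolist()}")
    d_inv_sqrt = sp.diags(1.0 / np.sqrt(deg))
    a = g.adjacency.astype(np.float64)
    lap = sp.identity(g.num_vertices, format="csr") - d_inv_sqrt @ a @ d_inv_sqrt
    return lap.tocsr()


def _fix_sign(vec: np.ndarray) -> np.ndarray:
    """Deterministic eigenvector sign: entry of largest magnitude is positive."""
    k = int(np.argmax(np.abs(vec)))
    return -vec if vec[k] < 0 else vec


def spectral_coordinates(g: SurfaceGraph, d: int = 3) -> SpectralCoordinates:
    """Eigenvectors of the normalized Laplacian for the d smallest positive eigenvalues.

    The graph must be connected: with multiple components the zero eigenvalue
    is degenerate and "smallest positive" is ill-defined.
    """
    n = g.num_vertices
    if d >= n:
        raise ValueError(f"d={d} must be < number of vertices {n}")
    if not g.is_connected():
        raise ValueError("graph is disconnected; spectral coordinates undefined")
    lap = normalized_laplacian(g)
    if n <= 512:
        vals, vecs = np.linalg.eigh(lap.toarray())
        vals, vecs = vals[: d + 4], vecs[:, : d + 4]
    else:
        # shift-invert just below 0 targets the low end of the spectrum
        # (a 0 shift would factorize the exactly singular Laplacian)
        k = min(d + 4, n - 1)
        vals, vecs = sp.linalg.eigsh(lap, k=k, sigma=-1e-2, which="LM")
        order = np.argsort(vals)
        vals, vecs = vals[order], vecs[:, order]
    positive = vals > 1e-8
    if positive.sum() < d:
        raise ValueError("not enough strictly positive eigenvalues")
    idx = np.flatnonzero(positive)[:d]
    vecs = np.column_stack([_fix_sign(vecs[:, i]) for i in idx])
    vecs /= np.linalg.norm(vecs, axis=0, keepdims=True)
    return SpectralCoordinates(eigenvectors=vecs, eigenvalues=vals[idx].copy())


def align_spectral(
    template: SpectralCoordinates, subject: SpectralCoordinates
) -> tuple[SpectralCoordinates, np.ndarray, np.ndarray]:
    """Reorder and sign-flip subject eigenvectors to best match a template.

    The cost of pairing template column ``i`` with subject column ``j`` is the
    Pearson correlation distance ``1 - |r_ij|``; the Hungarian algorithm finds
    the one-to-one column assignment of minimum total cost, and each matched
    column takes the sign that makes its correlation positive.

    Returns
    -------
    aligned : SpectralCoordinates
        Subject coordinates with columns permuted/flipped into template order.
    permutation : ndarray
        ``permutation[i]`` is the subject column matched to template column i.
    signs : ndarray
        The ±1 sign applied to each matched column.
    """
    t = np.asarray(template.eigenvectors, dtype=np.float64)
    s = np.asarray(subject.eigenvectors, dtype=np.float64)
    if t.shape != s.shape:
        raise ValueError(f"shape mismatch: template {t.shape} vs subject {s.shape}")
    tc = t - t.mean(axis=0)
    sc = s - s.mean(axis=0)
    t_sd = tc.std(axis=0)
    s_sd = sc.std(axis=0)
    if np.any(t_sd < 1e-14) or np.any(s_sd < 1e-14):
        raise ValueError("zero-variance eigenvector column; correlation undefined")
    r = (tc / t_sd).T @ (sc / s_sd) / t.shape[0]  # d x d Pearson correlations
    cost = 1.0 - np.abs(r)
    rows, cols = linear_sum_assignment(cost)
    perm = cols[np.argsort(rows)]
    signs = np.sign(r[np.arange(len(perm)), perm])
    signs[signs == 0] = 1.0
    aligned_vecs = s[:, perm] * signs
    return (
        SpectralCoordinates(
            eigenvectors=aligned_vecs,
            eigenvalues=np.asarray(subject.eigenvalues)[perm].copy(),
        ),
        perm,
        signs,
    )


def geodesic_hops(g: SurfaceGraph, sources: np.ndarray) -> np.ndarray:
    """Breadth-first hop distance from every vertex to the nearest source vertex."""
    sources = np.asarray(sources, dtype=np.int64).ravel()
    if sources.size == 0:
        raise ValueError("empty source set")
    n = g.num_vertices
    dist = np.full(n, -1, dtype=np.int64)
    dist[sources] = 0
    frontier = np.unique(sources)
    adj = g.adjacency
    hop = 0
    while frontier.size:
        hop += 1
        # all neighbors of the current frontier not yet assigned a distance
        nxt = np.unique(adj[frontier].indices)
        nxt = nxt[dist[nxt] < 0]
        dist[nxt] = hop
        frontier = nxt
    return dist
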