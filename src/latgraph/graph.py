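"""Surface graph construction and the positive-weight cotangent Laplacian.

The mesh becomes an undirected graph whose edges are the triangle edges.
Edge weights follow the cotangent discretisation of the Laplace-Beltrami
operator, with non-positive weights clamped to a small positive floor so
every retained edge has strictly positive weight and the Laplacian stays a
symmetric positive-semidefinite M-matrix with zero row sums.

Physiologically implausible connections are pruned by first quantizing the
surface from the observations (nearest-labeled-vertex assignment) and then
removing every edge whose endpoint quantized values differ by at least a
jump threshold (default 50 ms) — the mechanism that lets the interpolant
respect "early-meets-late" discontinuities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .io import TriMesh
from .preprocess import LabeledSet

__all__ = [
    "SurfaceGraph",
    "mesh_to_graph",
    "cotan_weights",
    "nn_quantize",
    "sparsify_edges",
    "build_surface_graph",
]

WEIGHT_FLOOR = 1e-6


def _assemble_laplacian(n: int, edges: np.ndarray, weights: np.ndarray) -> sp.csr_matrix:
    """L = D - W from an edge list; rows sum to zero by construction."""
    if len(edges) == 0:
        return sp.csr_matrix((n, n))
    i, j = edges[:, 0], edges[:, 1]
    w = weights
    rows = np.concatenate([i, j, i, j])
    cols = np.concatenate([j, i, i, j])
    vals = np.concatenate([-w, -w, w, w])
    lap = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    lap.sum_duplicates()
    return lap


@dataclass(frozen=True)
class SurfaceGraph:
    """Undirected weighted graph over mesh vertices with its Laplacian.

    ``edges`` is a (k, 2) array of sorted vertex pairs; ``weights`` aligns
    with it. ``removed_edges`` records pairs deleted by sparsification.
    """

    n: int
    edges: np.ndarray
    weights: np.ndarray | None = None
    laplacian: sp.csr_matrix | None = None
    removed_edges: np.ndarray = field(
        default_factory=lambda: np.empty((0, 2), dtype=np.int64)
    )

    def __post_init__(self):
        edges = np.ascontiguousarray(np.asarray(self.edges, dtype=np.int64)).reshape(-1, 2)
        if len(edges) and (edges.min() < 0 or edges.max() >= self.n):
            raise ValueError("edge index out of range")
        edges = np.sort(edges, axis=1)
        removed = np.ascontiguousarray(
            np.asarray(self.removed_edges, dtype=np.int64)
        ).reshape(-1, 2)
        if len(removed):
            removed = np.sort(removed, axis=1)
            both = {tuple(e) for e in edges} & {tuple(e) for e in removed}
            if both:
                raise ValueError(f"edge {sorted(both)[0]} both retained and removed")
        if self.weights is not None:
            w = np.ascontiguousarray(np.asarray(self.weights, dtype=float))
            if w.shape != (len(edges),):
                raise ValueError("weights must align with edges")
            if len(w) and w.min() <= 0:
                raise ValueError("retained edge with non-positive weight")
            object.__setattr__(self, "weights", w)
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "removed_edges", removed)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def with_weights(self, weights: np.ndarray) -> "SurfaceGraph":
        weights = np.asarray(weights, dtype=float)
        lap = _assemble_laplacian(self.n, self.edges, weights)
        return SurfaceGraph(self.n, self.edges, weights, lap, self.removed_edges)


def mesh_to_graph(mesh: TriMesh) -> SurfaceGraph:
    """Edge set of the mesh: two vertices are adjacent iff they share a face."""
    f = mesh.faces
    pairs = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [0, 2]]])
    pairs = np.unique(np.sort(pairs, axis=1), axis=0)
    return SurfaceGraph(mesh.n_vertices, pairs)


def _face_cotangents(verts: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """cot of the angle at each face corner, (t, 3) aligned with face columns."""
    p0, p1, p2 = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    cots = np.empty((len(faces), 3))
    for c, (a, b, o) in enumerate(((p1, p2, p0), (p2, p0, p1), (p0, p1, p2))):
        u = a - o
        v = b - o
        cross = np.linalg.norm(np.cross(u, v), axis=1)
        dot = np.einsum("ij,ij->i", u, v)
        cots[:, c] = dot / cross
    return cots


def cotan_weights(mesh: TriMesh, floor: float = WEIGHT_FLOOR) -> SurfaceGraph:
    """Cotangent edge weights, clamped to a positive floor, and L = D - W.

    w_ij = 1/2 * sum over faces containing edge (i, j) of cot(opposite
    angle); boundary edges get the single half-cotangent.  Any w_ij <= 0
    (obtuse configurations) is replaced by ``floor`` so that positivity —
    and with it the M-matrix structure of L — is preserved.
    """
    verts, faces = mesh.vertices, mesh.faces
    areas = 0.5 * np.linalg.norm(
        np.cross(verts[faces[:, 1]] - verts[faces[:, 0]], verts[faces[:, 2]] - verts[faces[:, 0]]),
        axis=1,
    )
    if (areas < 1e-12).any():
        bad = int(np.argmin(areas))
        raise ValueError(f"degenerate face {bad} (area {areas[bad]:.3e} mm^2)")
    cots = _face_cotangents(verts, faces)
    graph = mesh_to_graph(mesh)
    acc: dict[tuple[int, int], float] = {tuple(e): 0.0 for e in graph.edges}
    # corner c is opposite the edge formed by the other two corners
    opp = {0: (1, 2), 1: (0, 2), 2: (0, 1)}
    for c, (a, b) in opp.items():
        for t in range(len(faces)):
            e = tuple(sorted((faces[t, a], faces[t, b])))
            acc[e] += 0.5 * cots[t, c]
    weights = np.array([acc[tuple(e)] for e in graph.edges])
    weights[weights <= 0] = floor
    return graph.with_weights(weights)


def nn_quantize(mesh: TriMesh, labels: LabeledSet) -> np.ndarray:
    """Per-vertex LAT from the Euclidean-nearest labeled vertex.

    Labeled vertices keep their own value; ties break to the lowest labeled
    vertex index.  Returns an (n,) ms array whose entries all equal some
    observed value.
    """
    order = np.argsort(labels.vertex_indices)
    lab_idx = labels.vertex_indices[order]
    lab_val = labels.values[order]
    tree = cKDTree(mesh.vertices[lab_idx])
    k = min(2, len(lab_idx))
    dist, pos = tree.query(mesh.vertices, k=k)
    dist, pos = np.atleast_2d(dist.T).T, np.atleast_2d(pos.T).T
    out = lab_val[pos[:, 0]]
    if k == 2:
        # deterministic tie-break: lowest labeled vertex index at minimal distance
        tied = np.where(dist[:, 1] - dist[:, 0] <= 1e-12)[0]
        for v in tied:
            cand = tree.query_ball_point(mesh.vertices[v], dist[v, 0] + 1e-12)
            if cand:
                out[v] = lab_val[min(cand)]
    out[lab_idx] = lab_val
    return out


def sparsify_edges(
    graph: SurfaceGraph, quantized: np.ndarray, delta_lat: float = 50.0
) -> SurfaceGraph:
    """Remove edges whose quantized endpoint values jump by >= ``delta_lat`` ms.

    Surviving edges keep their cotangent weights; the Laplacian diagonal is
    reassembled so row sums stay zero.
    """
    quantized = np.asarray(quantized, dtype=float)
    if quantized.shape != (graph.n,):
        raise ValueError("quantized signal length must equal vertex count")
    if graph.weights is None:
        raise ValueError("graph has no weights; run cotan_weights first")
    jump = np.abs(quantized[graph.edges[:, 0]] - quantized[graph.edges[:, 1]])
    drop = jump >= delta_lat
    if not drop.any():
        return graph
    kept_e = graph.edges[~drop]
    kept_w = graph.weights[~drop]
    removed = np.concatenate([graph.removed_edges, graph.edges[drop]])
    lap = _assemble_laplacian(graph.n, kept_e, kept_w)
    return SurfaceGraph(graph.n, kept_e, kept_w, lap, removed)


def build_surface_graph(
    mesh: TriMesh,
    labels: LabeledSet | None = None,
    delta_lat: float | None = 50.0,
    floor: float = WEIGHT_FLOOR,
) -> SurfaceGraph:
    """Convenience pipeline: cotangent weights, then observation-driven pruning."""
    graph = cotan_weights(mesh, floor=floor)
    if labels is not None and delta_lat is not None and np.isfinite(delta_lat):
        graph = sparsify_edges(graph, nn_quantize(mesh, labels), delta_lat)
    return graph
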