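"""Observation pre-processing: vertex snapping and local-anomaly rejection.

Catheter sample coordinates rarely coincide with mesh vertices, so each
observation is snapped to its Euclidean-nearest vertex.  Observations that
disagree strongly with their spatial neighbours (annotation error, noise)
are then culled with a k-nearest-neighbour consistency rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .io import LATSamples, TriMesh

__all__ = ["LabeledSet", "snap_to_vertices", "remove_anomalous"]


@dataclass(frozen=True)
class LabeledSet:
    """LAT values attached to unique mesh vertices (the sampled vertex set)."""

    vertex_indices: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        idx = np.ascontiguousarray(np.asarray(self.vertex_indices, dtype=np.int64))
        vals = np.ascontiguousarray(np.asarray(self.values, dtype=float))
        if idx.ndim != 1 or vals.shape != idx.shape:
            raise ValueError("vertex_indices and values must be matching 1-d arrays")
        if len(idx) == 0:
            raise ValueError("labeled set is empty")
        if len(np.unique(idx)) != len(idx):
            raise ValueError("duplicate vertex index in labeled set")
        if idx.min() < 0:
            raise ValueError("negative vertex index")
        if not np.isfinite(vals).all():
            raise ValueError("non-finite LAT value")
        object.__setattr__(self, "vertex_indices", idx)
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)


def _nearest_vertex(vertices: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Index of the nearest vertex per coordinate; ties go to the lowest index."""
    tree = cKDTree(vertices)
    dist, idx = tree.query(coords)
    # re-resolve possible ties deterministically: among vertices at the
    # minimal distance (within 1e-12 mm slack) pick the lowest index
    out = np.empty(len(coords), dtype=np.int64)
    for i, (d, j) in enumerate(zip(dist, idx)):
        cand = tree.query_ball_point(coords[i], d + 1e-12)
        out[i] = min(cand) if cand else j
    return out


def snap_to_vertices(mesh: TriMesh, samples: LATSamples) -> LabeledSet:
    """Assign each observation to its Euclidean-nearest mesh vertex.

    Observations landing on the same vertex are merged by the arithmetic
    mean of their values.  Nearest-vertex ties break to the lowest index.
    """
    nearest = _nearest_vertex(mesh.vertices, samples.coords)
    uniq, inverse = np.unique(nearest, return_inverse=True)
    sums = np.bincount(inverse, weights=samples.values, minlength=len(uniq))
    counts = np.bincount(inverse, minlength=len(uniq))
    return LabeledSet(uniq, sums / counts)


def remove_anomalous(
    labeled: LabeledSet,
    mesh: TriMesh,
    k: int = 5,
    radius: float = 5.0,
    threshold: float = 30.0,
) -> LabeledSet:
    """Drop observations inconsistent with their local co-observations.

    An observation is removed when its value differs from the mean of its
    up-to-``k`` Euclidean-nearest co-observations within ``radius`` mm by
    strictly more than ``threshold`` ms.  Observations with no neighbour in
    range are kept, and all decisions are made against the original set in a
    single pass (no cascade).
    """
    coords = mesh.vertices[labeled.vertex_indices]
    m = len(labeled)
    if m == 1:
        return labeled
    tree = cKDTree(coords)
    # k+1 because each point finds itself at distance 0
    kq = min(k + 1, m)
    dist, idx = tree.query(coords, k=kq)
    dist = np.atleast_2d(dist)
    idx = np.atleast_2d(idx)
    keep = np.ones(m, dtype=bool)
    for i in range(m):
        neigh = [j for d, j in zip(dist[i], idx[i]) if j != i and d <= radius]
        if not neigh:
            continue
        if abs(labeled.values[i] - labeled.values[neigh].mean()) > threshold:
            keep[i] = False
    if keep.all():
        return labeled
    if not keep.any():
        raise ValueError("anomaly filter removed every observation")
    return LabeledSet(labeled.vertex_indices[keep], labeled.values[keep])
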