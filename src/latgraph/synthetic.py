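"""Synthetic activation maps for testing every stage without clinical data.

Two regimes are emulated at desk scale:

* **Focal activation** (premature ventricular complexes): a wavefront
  expands centrifugally from a single focus, so LAT grows with geodesic
  distance from the focus divided by a conduction velocity, plus
  measurement noise.  Geodesics are Dijkstra shortest paths over mesh edge
  lengths.
* **Early-meets-late**: one side of a cutting plane carries the focal
  field shifted by a large jump (>= 50 ms), producing adjacent vertices
  with drastically different LAT — the discontinuity that breaks smooth
  interpolators and that edge sparsification is designed to absorb.

Default scales target clinical electro-anatomic maps: meshes with a few
thousand vertices (~25 mm chamber radius), a few hundred observations,
conduction velocity below 1 mm/ms and a few ms of observation noise, with
the map shifted into the negative-ms range typical of LAT references.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra
import trimesh as _trimesh

from .io import LATSamples, TriMesh

__all__ = [
    "Discontinuity",
    "SyntheticSpec",
    "make_mesh",
    "simulate_focal_lat",
    "simulate_early_meets_late",
    "sample_observations",
]


@dataclass(frozen=True)
class Discontinuity:
    """Cutting plane (point + normal, mm) and the LAT jump across it (ms)."""

    jump_ms: float
    plane_point: tuple[float, float, float] = (0.0, 0.0, 0.0)
    plane_normal: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self):
        if self.jump_ms < 50.0:
            raise ValueError("jump_ms must be >= 50 ms to qualify as early-meets-late")
        if np.linalg.norm(self.plane_normal) == 0:
            raise ValueError("plane normal must be nonzero")


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator settings; defaults emulate a PVC map on a small chamber."""

    shape: str = "icosphere"
    subdivisions: int = 4
    radius: float = 25.0
    focus_vertex: int | str = "random"
    conduction_velocity: float = 0.8
    noise_sd: float = 3.0
    lat_min: float = -150.0
    discontinuity: Optional[Discontinuity] = None
    seed: int = 0

    def __post_init__(self):
        if self.shape not in ("icosphere", "ellipsoid", "cylinder"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.subdivisions < 1 and self.shape != "icosphere":
            raise ValueError("subdivisions must be >= 1")
        if self.subdivisions < 0:
            raise ValueError("subdivisions must be >= 0")
        if self.conduction_velocity <= 0:
            raise ValueError("conduction velocity must be positive (mm/ms)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def make_mesh(spec: SyntheticSpec) -> TriMesh:
    """Build the requested surface (icosphere 10*4^k + 2 vertices, scaled
    icosphere ellipsoid, or capped cylinder)."""
    if spec.shape == "icosphere":
        tm = _trimesh.creation.icosphere(subdivisions=spec.subdivisions, radius=spec.radius)
    elif spec.shape == "ellipsoid":
        tm = _trimesh.creation.icosphere(subdivisions=spec.subdivisions, radius=1.0)
        tm.vertices = tm.vertices * (np.array([1.0, 0.75, 0.55]) * spec.radius)
    else:  # cylinder
        tm = _trimesh.creation.cylinder(
            radius=spec.radius,
            height=2.0 * spec.radius,
            sections=4 * 2**spec.subdivisions,
        )
    return TriMesh(np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces))


def _edge_length_graph(mesh: TriMesh) -> sp.csr_matrix:
    f = mesh.faces
    pairs = np.unique(
        np.sort(np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [0, 2]]]), axis=1), axis=0
    )
    lengths = np.linalg.norm(mesh.vertices[pairs[:, 0]] - mesh.vertices[pairs[:, 1]], axis=1)
    n = mesh.n_vertices
    return sp.coo_matrix(
        (
            np.concatenate([lengths, lengths]),
            (
                np.concatenate([pairs[:, 0], pairs[:, 1]]),
                np.concatenate([pairs[:, 1], pairs[:, 0]]),
            ),
        ),
        shape=(n, n),
    ).tocsr()


def _resolve_focus(mesh: TriMesh, spec: SyntheticSpec, rng: np.random.Generator) -> int:
    if spec.focus_vertex == "random":
        return int(rng.integers(mesh.n_vertices))
    focus = int(spec.focus_vertex)
    if not 0 <= focus < mesh.n_vertices:
        raise ValueError(f"focus vertex {focus} out of range [0, {mesh.n_vertices})")
    return focus


def simulate_focal_lat(mesh: TriMesh, spec: SyntheticSpec) -> np.ndarray:
    """Per-vertex LAT (ms) of a focal wavefront: geodesic distance from the
    focus over conduction velocity, plus Gaussian noise, shifted so the map
    minimum sits at ``spec.lat_min`` (noiseless focus = map minimum)."""
    rng = np.random.default_rng(spec.seed)
    focus = _resolve_focus(mesh, spec, rng)
    dist = dijkstra(_edge_length_graph(mesh), indices=focus)
    if not np.isfinite(dist).all():
        raise ValueError(
            f"mesh component unreachable from focus {focus} (disconnected mesh)"
        )
    lat = dist / spec.conduction_velocity
    if spec.noise_sd > 0:
        lat = lat + rng.normal(0.0, spec.noise_sd, mesh.n_vertices)
    return lat + (spec.lat_min - lat.min())


def simulate_early_meets_late(mesh: TriMesh, spec: SyntheticSpec) -> np.ndarray:
    """Focal field plus a plane-bounded jump, giving adjacent vertices with
    an LAT difference of at least 50 ms across the boundary."""
    if spec.discontinuity is None:
        raise ValueError("spec.discontinuity must be set for an early-meets-late field")
    disc = spec.discontinuity
    field_vals = simulate_focal_lat(mesh, spec)
    normal = np.asarray(disc.plane_normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    side = (mesh.vertices - np.asarray(disc.plane_point, dtype=float)) @ normal > 0
    if side.all() or not side.any():
        raise ValueError("boundary plane misses the mesh (all vertices on one side)")
    field_vals = field_vals.copy()
    field_vals[side] += disc.jump_ms
    f = mesh.faces
    pairs = np.unique(
        np.sort(np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [0, 2]]]), axis=1), axis=0
    )
    crossing = side[pairs[:, 0]] != side[pairs[:, 1]]
    jumps = np.abs(field_vals[pairs[:, 0]] - field_vals[pairs[:, 1]])
    if not (jumps[crossing] >= 50.0).any():
        raise ValueError("no mesh edge crosses the boundary with a >= 50 ms jump")
    return field_vals


def sample_observations(
    mesh: TriMesh,
    field_values: np.ndarray,
    n_obs: int,
    seed: int,
    coord_jitter: float = 0.5,
) -> LATSamples:
    """Emulate catheter observations: values of the ground-truth field at
    ``n_obs`` distinct random vertices, with coordinates perturbed by
    isotropic Gaussian jitter (mm) so snapping is exercised."""
    field_values = np.asarray(field_values, dtype=float)
    if field_values.shape != (mesh.n_vertices,):
        raise ValueError("field length must equal vertex count")
    if not 1 <= n_obs <= mesh.n_vertices:
        raise ValueError("n_obs out of range")
    rng = np.random.default_rng(seed)
    idx = rng.choice(mesh.n_vertices, size=n_obs, replace=False)
    coords = mesh.vertices[idx]
    if coord_jitter > 0:
        coords = coords + rng.normal(0.0, coord_jitter, coords.shape)
    return LATSamples(coords, field_values[idx])
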