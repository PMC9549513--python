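"""Cross-validation harness: repeated random train/test splits of the
observation set, method comparison, and serialisable results.

Per repetition, ``m`` training observations are drawn from the sampled
vertex set with the clinical sub-sampling distribution; each requested
method interpolates from the identical training subset; MDE and NMSE are
scored on the complementary test subset, against the map-wide colour range
(ground-truth observation min/max) so repetitions are comparable.
Pre-processing (snapping, anomaly rejection) runs once per map, before any
repetition.  Everything is reproducible from the base seed (per-repetition
seeds are base + repetition index).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .graph import SurfaceGraph, cotan_weights, nn_quantize, sparsify_edges
from .interpolate import InterpConfig, InterpolationProblem, gpr_baseline, graph_interpolate
from .io import LATSamples, TriMesh
from .metric import ColormapRange, mde, nmse
from .preprocess import LabeledSet, remove_anomalous, snap_to_vertices
from .sampling import SamplingConfig, draw_subset, sampling_distribution

__all__ = ["EvalResult", "crossval", "sweep_m", "METHODS"]

METHODS = ("graph", "gpr")


@dataclass(frozen=True)
class EvalResult:
    """Per-repetition scores plus aggregates for one (map, m) experiment."""

    m: int
    reps: int
    seed: int
    methods: tuple[str, ...]
    mde_per_rep: dict[str, list[float]]
    nmse_per_rep: dict[str, list[float]]
    config: dict = dc_field(default_factory=dict)

    def mean_mde(self, method: str) -> float:
        return float(np.mean(self.mde_per_rep[method]))

    def std_mde(self, method: str) -> float:
        return float(np.std(self.mde_per_rep[method]))

    def mean_nmse(self, method: str) -> float:
        return float(np.mean(self.nmse_per_rep[method]))

    def std_nmse(self, method: str) -> float:
        return float(np.std(self.nmse_per_rep[method]))

    def to_dict(self) -> dict:
        return {
            "m": self.m,
            "reps": self.reps,
            "seed": self.seed,
            "methods": list(self.methods),
            "config": self.config,
            "per_rep": {
                meth: {
                    "mde": self.mde_per_rep[meth],
                    "nmse": self.nmse_per_rep[meth],
                }
                for meth in self.methods
            },
            "summary": {
                meth: {
                    "mde_mean": self.mean_mde(meth),
                    "mde_std": self.std_mde(meth),
                    "nmse_mean": self.mean_nmse(meth),
                    "nmse_std": self.std_nmse(meth),
                }
                for meth in self.methods
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)

    def per_rep_frame(self) -> pd.DataFrame:
        rows = []
        for meth in self.methods:
            for rep, (d, e) in enumerate(
                zip(self.mde_per_rep[meth], self.nmse_per_rep[meth])
            ):
                rows.append({"method": meth, "rep": rep, "mde": d, "nmse": e})
        return pd.DataFrame(rows)


def _preprocess(
    mesh: TriMesh,
    samples: LATSamples,
    anomaly_filter: bool,
    k: int,
    radius: float,
    threshold: float,
) -> LabeledSet:
    labeled = snap_to_vertices(mesh, samples)
    if anomaly_filter:
        labeled = remove_anomalous(labeled, mesh, k=k, radius=radius, threshold=threshold)
    return labeled


def crossval(
    mesh: TriMesh,
    samples: LATSamples,
    m: int,
    reps: int,
    methods: Sequence[str] = ("graph",),
    seed: int = 0,
    interp_config: InterpConfig | None = None,
    delta_lat: Optional[float] = 50.0,
    sampling_config: SamplingConfig | None = None,
    anomaly_filter: bool = True,
    anomaly_k: int = 5,
    anomaly_radius: float = 5.0,
    anomaly_threshold: float = 30.0,
    colormap_range: ColormapRange | None = None,
    base_graph: SurfaceGraph | None = None,
) -> EvalResult:
    """Repeated random-split evaluation of the requested methods.

    ``base_graph`` may carry a precomputed cotangent-weighted graph for the
    mesh to avoid repeated assembly across calls (it is never sparsified in
    place; pruning happens per repetition from the training labels).
    """
    for meth in methods:
        if meth not in METHODS:
            raise ValueError(f"unknown method {meth!r}; expected subset of {METHODS}")
    interp_config = interp_config or InterpConfig()
    sampling_config = sampling_config or SamplingConfig()

    labeled = _preprocess(
        mesh, samples, anomaly_filter, anomaly_k, anomaly_radius, anomaly_threshold
    )
    if not m < len(labeled):
        raise ValueError(
            f"m = {m} must be smaller than the usable observation count {len(labeled)}"
        )
    crange = colormap_range or ColormapRange.from_values(labeled.values)
    if base_graph is None or base_graph.weights is None:
        base_graph = cotan_weights(mesh)

    dist = sampling_distribution(labeled.values, sampling_config)
    mde_per: dict[str, list[float]] = {meth: [] for meth in methods}
    nmse_per: dict[str, list[float]] = {meth: [] for meth in methods}
    for rep in range(reps):
        rep_seed = seed + rep
        train_pos = draw_subset(dist, m, rep_seed)
        test_mask = np.ones(len(labeled), dtype=bool)
        test_mask[train_pos] = False
        train = LabeledSet(labeled.vertex_indices[train_pos], labeled.values[train_pos])
        test_idx = labeled.vertex_indices[test_mask]
        test_val = labeled.values[test_mask]
        for meth in methods:
            if meth == "graph":
                graph = base_graph
                if delta_lat is not None and np.isfinite(delta_lat):
                    graph = sparsify_edges(graph, nn_quantize(mesh, train), delta_lat)
                problem = InterpolationProblem.from_labels(
                    graph, train.vertex_indices, train.values
                )
                estimate = graph_interpolate(problem, interp_config)[test_idx]
            else:  # gpr
                estimate = gpr_baseline(
                    mesh.vertices[train.vertex_indices],
                    train.values,
                    mesh.vertices[test_idx],
                )
            mde_per[meth].append(mde(estimate, test_val, crange))
            nmse_per[meth].append(nmse(estimate, test_val))

    return EvalResult(
        m=m,
        reps=reps,
        seed=seed,
        methods=tuple(methods),
        mde_per_rep=mde_per,
        nmse_per_rep=nmse_per,
        config={
            "alpha": interp_config.alpha,
            "beta": interp_config.beta,
            "delta_lat": None if delta_lat is None else float(delta_lat),
            "lambda1": sampling_config.lambda1,
            "lambda2": sampling_config.lambda2,
            "s_min": crange.s_min,
            "s_max": crange.s_max,
            "n_observations": int(len(labeled)),
            "anomaly_filter": bool(anomaly_filter),
        },
    )


def sweep_m(
    mesh: TriMesh,
    samples: LATSamples,
    m_values: Sequence[int],
    reps: int,
    methods: Sequence[str] = ("graph",),
    seed: int = 0,
    **kwargs,
) -> list[EvalResult]:
    """One :func:`crossval` per requested training-set size.

    Each m gets an independent block of the base seed stream (offset by
    10000 per position) so results are reproducible yet independent.
    """
    if "base_graph" not in kwargs or kwargs.get("base_graph") is None:
        kwargs = dict(kwargs)
        kwargs["base_graph"] = cotan_weights(mesh)
    return [
        crossval(mesh, samples, m, reps, methods, seed + 10000 * i, **kwargs)
        for i, m in enumerate(m_values)
    ]
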