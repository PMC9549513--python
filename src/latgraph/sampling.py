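"""Clinically realistic non-uniform sub-sampling of LAT observations.

During mapping, technicians densely sample mid-to-early activation while
searching for the earliest-activation site, occasionally jumping elsewhere,
so every observation keeps a non-trivial selection probability.  The
distribution emulating this behaviour is built from the observation values
alone:

    x_i = s_i + |s_min|          (only if any value is negative)
    x'  = x_min + lambda1 * x_avg        (intended densest value)
    d_i = |x_i - x'|
    r_i = lambda2 * (d_max - d_i) + 1    (>= 1 by construction)
    f_i = floor(r_i)                     (integer repetitions, >= 1)
    p_i = f_i / sum(f_i)

lambda1 = 0.5 places the densest sampling halfway between the earliest and
the mean activation; lambda2 = 0.25 gives a slowly decaying slope so that
no observation becomes vanishingly improbable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SamplingConfig", "SamplingDistribution", "sampling_distribution", "draw_subset"]


@dataclass(frozen=True)
class SamplingConfig:
    """lambda1 positions the sampling peak between earliest and mean
    activation; lambda2 (per ms) sets the slope of the probability decay."""

    lambda1: float = 0.5
    lambda2: float = 0.25

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("lambda1 and lambda2 must be >= 0")


@dataclass(frozen=True)
class SamplingDistribution:
    """All intermediate quantities of the sampling construction."""

    x: np.ndarray
    x_peak: float
    d: np.ndarray
    d_max: float
    r: np.ndarray
    f: np.ndarray
    p: np.ndarray

    def __post_init__(self):
        if (self.x < 0).any():
            raise ValueError("shifted values must be nonnegative")
        if (self.r < 1 - 1e-12).any() or (self.f < 1).any():
            raise ValueError("every raw score must be >= 1 (nonzero probability)")
        if abs(self.p.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1")

    def __len__(self) -> int:
        return len(self.p)


def sampling_distribution(
    values: np.ndarray, config: SamplingConfig | None = None
) -> SamplingDistribution:
    """Build the non-uniform selection distribution over observations."""
    config = config or SamplingConfig()
    values = np.asarray(values, dtype=float).ravel()
    if len(values) == 0:
        raise ValueError("empty observation set")
    x = values + abs(values.min()) if values.min() < 0 else values.copy()
    x_peak = float(x.min() + config.lambda1 * x.mean())
    d = np.abs(x - x_peak)
    d_max = float(d.max())
    r = config.lambda2 * (d_max - d) + 1.0
    f = np.floor(r).astype(np.int64)
    p = f / f.sum()
    return SamplingDistribution(x, x_peak, d, d_max, r, f, p)


def draw_subset(dist: SamplingDistribution, m: int, seed: int) -> np.ndarray:
    """Draw ``m`` distinct observation indices without replacement.

    Each successive draw picks an index with probability proportional to the
    integer repetition counts ``f`` of the still-available observations, so
    repeated draws emulate uniform sampling of the repetition list while
    returning distinct indices.  Deterministic in (seed, inputs).
    """
    n = len(dist)
    if not 1 <= m <= n:
        raise ValueError(f"m must be in [1, {n}], got {m}")
    rng = np.random.default_rng(seed)
    available = np.arange(n)
    weights = dist.f.astype(float).copy()
    out = np.empty(m, dtype=np.int64)
    for k in range(m):
        p = weights[available] / weights[available].sum()
        pick = rng.choice(len(available), p=p)
        out[k] = available[pick]
        available = np.delete(available, pick)
    return out
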