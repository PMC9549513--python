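"""Perceptual map-difference metric: Mean Delta-E (MDE), plus NMSE.

A clinician reads an activation map through its colours, so interpolation
error is measured where it is perceived: each LAT value is mapped to its
viridis colour over a fixed display range [s_min, s_max], colours are
converted to CIELAB (D65), and estimated-vs-true colours are compared with
the CIEDE2000 colour-difference formula.  MDE is the mean of those
per-point differences.  Because out-of-range values clamp to the colormap
endpoints, restricting the display range makes any point whose estimate
and truth both fall outside it on the same side contribute exactly zero —
which is how range-restricted map reading is emulated.

NMSE (residual sum of squares over centred total sum of squares of the
truth) is kept as the conventional secondary metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._viridis import VIRIDIS_TABLE

__all__ = [
    "ColormapRange",
    "ColorDifferenceParams",
    "lat_to_color",
    "srgb_to_lab",
    "ciede2000",
    "mde",
    "nmse",
]


@dataclass(frozen=True)
class ColormapRange:
    """Display range [s_min, s_max] in ms used for colour assignment."""

    s_min: float
    s_max: float

    def __post_init__(self):
        if not self.s_min < self.s_max:
            raise ValueError("require s_min < s_max")

    @classmethod
    def from_values(cls, values: np.ndarray) -> "ColormapRange":
        values = np.asarray(values, dtype=float)
        return cls(float(values.min()), float(values.max()))


@dataclass(frozen=True)
class ColorDifferenceParams:
    """CIEDE2000 weighting factors; the standard default is 1, 1, 1."""

    k_l: float = 1.0
    k_c: float = 1.0
    k_h: float = 1.0

    def __post_init__(self):
        if min(self.k_l, self.k_c, self.k_h) <= 0:
            raise ValueError("weighting factors must be positive")


def lat_to_color(values: np.ndarray, crange: ColormapRange) -> np.ndarray:
    """Map ms values to viridis sRGB colours over ``crange``.

    The value position (v - s_min) / (s_max - s_min) is clamped to [0, 1]
    and looked up in the embedded 256-entry table with linear interpolation
    between adjacent entries.  Returns an (..., 3) array in [0, 1].
    """
    values = np.asarray(values, dtype=float)
    t = np.clip((values - crange.s_min) / (crange.s_max - crange.s_min), 0.0, 1.0)
    x = t * (len(VIRIDIS_TABLE) - 1)
    i0 = np.minimum(np.floor(x).astype(int), len(VIRIDIS_TABLE) - 2)
    frac = (x - i0)[..., None]
    return (1.0 - frac) * VIRIDIS_TABLE[i0] + frac * VIRIDIS_TABLE[i0 + 1]


# sRGB -> XYZ (linear, D65) and the D65 reference white
_SRGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
_D65 = np.array([0.95047, 1.0, 1.08883])


def srgb_to_lab(rgb: np.ndarray) -> np.ndarray:
    """Convert sRGB in [0, 1] to CIELAB (D65 white, 2-degree observer)."""
    rgb = np.asarray(rgb, dtype=float)
    if rgb.shape[-1] != 3:
        raise ValueError("last axis must hold r, g, b")
    if rgb.min() < -1e-12 or rgb.max() > 1 + 1e-12:
        raise ValueError("sRGB components must lie in [0, 1]")
    linear = np.where(rgb <= 0.04045, rgb / 12.92, ((rgb + 0.055) / 1.055) ** 2.4)
    xyz = linear @ _SRGB_TO_XYZ.T / _D65
    eps = (6.0 / 29.0) ** 3
    f = np.where(xyz > eps, np.cbrt(xyz), xyz / (3 * (6.0 / 29.0) ** 2) + 4.0 / 29.0)
    lab = np.empty_like(xyz)
    lab[..., 0] = 116.0 * f[..., 1] - 16.0
    lab[..., 1] = 500.0 * (f[..., 0] - f[..., 1])
    lab[..., 2] = 200.0 * (f[..., 1] - f[..., 2])
    return lab


def ciede2000(
    lab1: np.ndarray,
    lab2: np.ndarray,
    params: ColorDifferenceParams | None = None,
) -> np.ndarray:
    """CIEDE2000 colour difference between CIELAB colours (vectorised).

    Implements the standard formula with lightness/chroma/hue compensation
    terms S_L, S_C, S_H and the hue-rotation term R_T; ``params`` carries
    the k_L, k_C, k_H weighting factors.
    """
    params = params or ColorDifferenceParams()
    lab1 = np.asarray(lab1, dtype=float)
    lab2 = np.asarray(lab2, dtype=float)
    l1, a1, b1 = lab1[..., 0], lab1[..., 1], lab1[..., 2]
    l2, a2, b2 = lab2[..., 0], lab2[..., 1], lab2[..., 2]

    c1 = np.hypot(a1, b1)
    c2 = np.hypot(a2, b2)
    cbar = 0.5 * (c1 + c2)
    g = 0.5 * (1.0 - np.sqrt(cbar**7 / (cbar**7 + 25.0**7)))
    a1p = (1.0 + g) * a1
    a2p = (1.0 + g) * a2
    c1p = np.hypot(a1p, b1)
    c2p = np.hypot(a2p, b2)
    h1p = np.degrees(np.arctan2(b1, a1p)) % 360.0
    h2p = np.degrees(np.arctan2(b2, a2p)) % 360.0
    h1p = np.where((np.abs(b1) < 1e-300) & (np.abs(a1p) < 1e-300), 0.0, h1p)
    h2p = np.where((np.abs(b2) < 1e-300) & (np.abs(a2p) < 1e-300), 0.0, h2p)

    dlp = l2 - l1
    dcp = c2p - c1p
    zero_chroma = (c1p * c2p) == 0.0
    dh = h2p - h1p
    dh = np.where(dh > 180.0, dh - 360.0, dh)
    dh = np.where(dh < -180.0, dh + 360.0, dh)
    dh = np.where(zero_chroma, 0.0, dh)
    dhp = 2.0 * np.sqrt(c1p * c2p) * np.sin(np.radians(dh) / 2.0)

    lbar = 0.5 * (l1 + l2)
    cbarp = 0.5 * (c1p + c2p)
    hsum = h1p + h2p
    habs = np.abs(h1p - h2p)
    hbar = np.where(
        habs <= 180.0,
        0.5 * hsum,
        np.where(hsum < 360.0, 0.5 * (hsum + 360.0), 0.5 * (hsum - 360.0)),
    )
    hbar = np.where(zero_chroma, hsum, hbar)

    t = (
        1.0
        - 0.17 * np.cos(np.radians(hbar - 30.0))
        + 0.24 * np.cos(np.radians(2.0 * hbar))
        + 0.32 * np.cos(np.radians(3.0 * hbar + 6.0))
        - 0.20 * np.cos(np.radians(4.0 * hbar - 63.0))
    )
    dtheta = 30.0 * np.exp(-(((hbar - 275.0) / 25.0) ** 2))
    r_c = 2.0 * np.sqrt(cbarp**7 / (cbarp**7 + 25.0**7))
    s_l = 1.0 + 0.015 * (lbar - 50.0) ** 2 / np.sqrt(20.0 + (lbar - 50.0) ** 2)
    s_c = 1.0 + 0.045 * cbarp
    s_h = 1.0 + 0.015 * cbarp * t
    r_t = -np.sin(np.radians(2.0 * dtheta)) * r_c

    tl = dlp / (params.k_l * s_l)
    tc = dcp / (params.k_c * s_c)
    th = dhp / (params.k_h * s_h)
    return np.sqrt(tl**2 + tc**2 + th**2 + r_t * tc * th)


def mde(
    estimates: np.ndarray,
    truth: np.ndarray,
    crange: ColormapRange,
    params: ColorDifferenceParams | None = None,
) -> float:
    """Mean CIEDE2000 difference between estimated and true map colours."""
    estimates = np.asarray(estimates, dtype=float).ravel()
    truth = np.asarray(truth, dtype=float).ravel()
    if estimates.shape != truth.shape:
        raise ValueError("estimates and truth must have equal length")
    if len(truth) == 0:
        raise ValueError("empty input")
    lab_est = srgb_to_lab(lat_to_color(estimates, crange))
    lab_tru = srgb_to_lab(lat_to_color(truth, crange))
    return float(ciede2000(lab_est, lab_tru, params).mean())


def nmse(estimates: np.ndarray, truth: np.ndarray) -> float:
    """Sum of squared errors over the centred sum of squares of the truth."""
    estimates = np.asarray(estimates, dtype=float).ravel()
    truth = np.asarray(truth, dtype=float).ravel()
    if estimates.shape != truth.shape:
        raise ValueError("estimates and truth must have equal length")
    denom = float(((truth - truth.mean()) ** 2).sum())
    if denom == 0.0:
        raise ValueError("zero-variance ground truth")
    return float(((estimates - truth) ** 2).sum() / denom)
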