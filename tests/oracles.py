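"""Independent brute-force oracles used to cross-check the counting module.

These reimplement the counting semantics naively (pure-Python walks, per-point
bilinear lookups) so the vectorized implementations can be checked for exact
agreement on random masks.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage

from woundstereo.counting import SMOOTHING_SIGMA_PX

ORACLE_STEP_UM = 0.05


def _resample_naive(vertices: np.ndarray, step: float) -> list[tuple[float, float]]:
    """Equal-arc-length resampling of a polyline, endpoint included."""
    cum = [0.0]
    for (x0, y0), (x1, y1) in zip(vertices[:-1], vertices[1:]):
        cum.append(cum[-1] + math.hypot(x1 - x0, y1 - y0))
    total = cum[-1]
    n = max(int(math.ceil(total / step)), 1)
    out = []
    j = 0
    for k in range(n + 1):
        s = total * k / n
        while j < len(cum) - 2 and cum[j + 1] < s:
            j += 1
        seg = cum[j + 1] - cum[j]
        t = 0.0 if seg == 0 else (s - cum[j]) / seg
        x = vertices[j][0] + t * (vertices[j + 1][0] - vertices[j][0])
        y = vertices[j][1] + t * (vertices[j + 1][1] - vertices[j][1])
        out.append((x, y))
    return out


def _bilinear_inside(m: np.ndarray, x: float, y: float, ps: float) -> bool:
    h, w = m.shape
    fx = min(max(x / ps - 0.5, 0.0), w - 1.0)
    fy = min(max(y / ps - 0.5, 0.0), h - 1.0)
    x0, y0 = int(math.floor(fx)), int(math.floor(fy))
    x1, y1 = min(x0 + 1, w - 1), min(y0 + 1, h - 1)
    tx, ty = fx - x0, fy - y0
    v = (
        m[y0, x0] * (1 - tx) * (1 - ty)
        + m[y0, x1] * tx * (1 - ty)
        + m[y1, x0] * (1 - tx) * ty
        + m[y1, x1] * tx * ty
    )
    return v >= 0.5


def oracle_curve_counts(
    mask: np.ndarray,
    system,
    pixel_size: float,
    origin: tuple[float, float] = (0.0, 0.0),
    runs: bool = False,
) -> int:
    """Dense-sampling (0.05 μm) brute-force transition or run count."""
    m = ndimage.gaussian_filter(np.asarray(mask, float), SMOOTHING_SIGMA_PX)
    total = 0
    for arc in system.arcs:
        pts = _resample_naive(arc.vertices, ORACLE_STEP_UM)
        states = [
            _bilinear_inside(m, x + origin[0], y + origin[1], pixel_size) for x, y in pts
        ]
        if runs:
            count = 1 if states[0] else 0
            for a, b in zip(states[:-1], states[1:]):
                if not a and b:
                    count += 1
        else:
            count = sum(1 for a, b in zip(states[:-1], states[1:]) if a != b)
        total += count
    return total


def oracle_point_hits(
    cell_mask: np.ndarray, tissue_mask: np.ndarray, grid: np.ndarray, pixel_size: float
) -> tuple[int, int]:
    """Per-point nearest-pixel membership, evaluated independently."""
    P_p = P_T = 0
    for x, y in grid:
        c = int(math.floor(x / pixel_size))
        r = int(math.floor(y / pixel_size))
        if cell_mask[r, c]:
            P_p += 1
        if tissue_mask[r, c]:
            P_T += 1
    return P_p, P_T


def random_blob_mask(seed: int, shape=(160, 160), sigma: float = 4.0) -> np.ndarray:
    """Smooth random blobs: thresholded low-pass Gaussian noise."""
    rng = np.random.default_rng(seed)
    noise = ndimage.gaussian_filter(rng.normal(size=shape), sigma)
    return noise > np.quantile(noise, 0.7)
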