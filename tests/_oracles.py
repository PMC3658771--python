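"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as plain Python loops over pixels
and closed-form geometry, sharing no code path with the vectorized
implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np


def naive_total_energy(phi, image, g, mask, c1, c2, params) -> float:
    """Pixel-by-pixel double loop over the five energy terms.

    Forward differences with replicate edges (zero at the last row/column),
    the division guard inside the square root, and the arctangent
    Heaviside / Cauchy Dirac evaluated from their closed forms.
    """
    h, w = image.shape
    s_int = params.intensity_scale
    e = 0.0
    for i in range(h):
        for j in range(w):
            p = float(phi[i, j])
            u = float(image[i, j]) / s_int
            k1 = c1 / s_int
            k2 = c2 / s_int
            gx = float(phi[i + 1, j] - p) if i + 1 < h else 0.0
            gy = float(phi[i, j + 1] - p) if j + 1 < w else 0.0
            s = math.sqrt(gx * gx + gy * gy + params.eps_d)
            h_in = 0.5 * (1.0 + (2.0 / math.pi) * math.atan(-p / params.eps))
            h_out = 0.5 * (1.0 + (2.0 / math.pi) * math.atan(p / params.eps))
            dirac = params.eps / (math.pi * (p * p + params.eps**2))
            m = 1.0 if mask[i, j] else 0.0
            e += params.lambda1 * (u - k1) ** 2 * h_in * m
            e += params.lambda2 * (u - k2) ** 2 * h_out * m
            e += params.mu * float(g[i, j]) * dirac * s
            e += params.v * float(g[i, j]) * h_in
            e += params.alpha * 0.5 * (s - 1.0) ** 2
    return e


def disk_sdf(shape, center, radius) -> np.ndarray:
    """Exact signed distance to a circle: negative inside, positive outside."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    d = np.sqrt((rr - center[0]) ** 2 + (cc - center[1]) ** 2)
    return d - radius


def polyline_length(poly: np.ndarray) -> float:
    """Sum of segment lengths of an (N, 2) polyline."""
    return float(np.sqrt(((poly[1:] - poly[:-1]) ** 2).sum(axis=1)).sum())
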