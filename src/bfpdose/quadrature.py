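"""Fixed-order Gauss-Legendre panel quadrature and Legendre helpers.

Transfer-matrix assembly uses deterministic fixed-order Gauss rules on
panels split at every point where an integration bound changes analytic
form (kinematic limits crossing group boundaries, the bremsstrahlung tip
ramp).  Splitting keeps the integrand smooth on each panel, so a 16-point
rule reaches quadrature error far below the 1e-6 oracle tolerance.
"""

from __future__ import annotations

import numpy as np

_GL_CACHE: dict = {}


def gl_nodes(n: int):
    """Nodes/weights of the n-point Gauss-Legendre rule on [-1, 1]."""
    if n not in _GL_CACHE:
        _GL_CACHE[n] = np.polynomial.legendre.leggauss(n)
    return _GL_CACHE[n]


def panel_points(a, b, n=16):
    """Nodes and weights mapped to [a, b] (arrays broadcast over a, b)."""
    x, w = gl_nodes(n)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    half = 0.5 * (b - a)
    mid = 0.5 * (b + a)
    pts = mid[..., None] + half[..., None] * x
    wts = half[..., None] * w
    return pts, wts


def split_panels(a: float, b: float, breaks) -> list:
    """Sub-intervals of [a, b] split at interior breakpoints."""
    if b <= a:
        return []
    pts = sorted({float(t) for t in breaks if a < t < b})
    edges = [a] + pts + [b]
    return list(zip(edges[:-1], edges[1:]))


def legendre_all(L: int, x: np.ndarray) -> np.ndarray:
    """P_l(x) for l = 0..L, stacked on a new leading axis."""
    x = np.asarray(x, dtype=float)
    out = np.empty((L + 1,) + x.shape)
    out[0] = 1.0
    if L >= 1:
        out[1] = x
    for l in range(1, L):
        out[l + 1] = ((2 * l + 1) * x * out[l] - l * out[l - 1]) / (l + 1)
    return out
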