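"""Exact polygonal linking number, independent of the package kernel.

For two closed polygons the linking number equals the sum over all
segment pairs of the signed solid angle subtended by the quadrilateral
of the four endpoints (Klenin-Langowski closed form), divided by 4π.
Unlike the midpoint quadrature in the package, this is exact for
polygons: it returns the integer up to floating-point noise, and is
used as the brute-force reference in the tests only.
"""

from __future__ import annotations

import numpy as np


def _unit(v: np.ndarray, eps: float = 1e-12) -> tuple[np.ndarray, np.ndarray]:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    ok = n[..., 0] > eps
    safe = np.where(n > eps, n, 1.0)
    return v / safe, ok


def exact_linking(curve1: np.ndarray, curve2: np.ndarray) -> float:
    """Exact Gauss linking number of two closed polygons (float ~ integer)."""
    p1 = np.asarray(curve1, float)
    p2 = np.roll(p1, -1, axis=0)
    q1 = np.asarray(curve2, float)
    q2 = np.roll(q1, -1, axis=0)

    r13 = q1[None, :, :] - p1[:, None, :]
    r14 = q2[None, :, :] - p1[:, None, :]
    r23 = q1[None, :, :] - p2[:, None, :]
    r24 = q2[None, :, :] - p2[:, None, :]

    n1, ok1 = _unit(np.cross(r13, r14))
    n2, ok2 = _unit(np.cross(r14, r24))
    n3, ok3 = _unit(np.cross(r24, r23))
    n4, ok4 = _unit(np.cross(r23, r13))
    ok = ok1 & ok2 & ok3 & ok4  # degenerate quadrilaterals contribute zero

    def asin_dot(a, b):
        return np.arcsin(np.clip(np.einsum("ijk,ijk->ij", a, b), -1.0, 1.0))

    angle = asin_dot(n1, n2) + asin_dot(n2, n3) + asin_dot(n3, n4) + asin_dot(n4, n1)

    r12 = (p2 - p1)[:, None, :]
    r34 = (q2 - q1)[None, :, :]
    sign = np.sign(np.einsum("ijk,ijk->ij", np.cross(r34, r12), r13))

    return float(np.sum(np.where(ok, angle * sign, 0.0))) / (4.0 * np.pi)
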