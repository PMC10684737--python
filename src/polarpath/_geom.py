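"""Small vectorized 2-D geometry primitives shared across modules."""

from __future__ import annotations

import numpy as np


def segment_segment_distance(a0, a1, b0, b1):
    """Minimum Euclidean distance between segments [a0,a1] and [b0,b1].

    All inputs broadcast; last axis is (x, y). Degenerate (zero-length)
    segments are handled as points.
    """
    a0 = np.asarray(a0, dtype=float)
    a1 = np.asarray(a1, dtype=float)
    b0 = np.asarray(b0, dtype=float)
    b1 = np.asarray(b1, dtype=float)

    d1 = a1 - a0
    d2 = b1 - b0
    r = a0 - b0
    A = np.einsum("...i,...i->...", d1, d1)
    E = np.einsum("...i,...i->...", d2, d2)
    B = np.einsum("...i,...i->...", d1, d2)
    C = np.einsum("...i,...i->...", d1, r)
    F = np.einsum("...i,...i->...", d2, r)

    eps = 1e-12
    denom = A * E - B * B
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(denom > eps, np.clip((B * F - C * E) / np.where(denom > eps, denom, 1.0), 0.0, 1.0), 0.0)
        t = np.where(E > eps, np.clip((B * s + F) / np.where(E > eps, E, 1.0), 0.0, 1.0), 0.0)
        s = np.where(A > eps, np.clip((B * t - C) / np.where(A > eps, A, 1.0), 0.0, 1.0), s)

    pa = a0 + s[..., None] * d1
    pb = b0 + t[..., None] * d2
    return np.hypot(pa[..., 0] - pb[..., 0], pa[..., 1] - pb[..., 1])


def signed_angle(u, v):
    """Signed angle from vector u to vector v in (-pi, pi], broadcastable."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    cross = u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0]
    dot = u[..., 0] * v[..., 0] + u[..., 1] * v[..., 1]
    return np.arctan2(cross, dot)


def rotate_about(points, center, angle_rad):
    """Rotate points about a center by angle_rad (mathematical orientation)."""
    points = np.asarray(points, dtype=float)
    center = np.asarray(center, dtype=float)
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    d = points - center
    return np.stack(
        [center[..., 0] + c * d[..., 0] - s * d[..., 1],
         center[..., 1] + s * d[..., 0] + c * d[..., 1]],
        axis=-1,
    )
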