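"""Planar geometry primitives shared by the filament simulator and the trace analyses.

Conventions: points are ``(x, y)`` tuples or ``(n, 2)`` float arrays; angles are in
radians unless a function name says degrees.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "circle_intersection",
    "interior_angle",
    "rotate_about",
    "segment_to_segments_distance",
    "axial_difference_deg",
]

_EPS = 1e-12


def circle_intersection(c0, r0, c1, r1):
    """Intersection points of two circles, or ``None`` when they do not meet.

    Returns a pair of points (identical at tangency). Coincident centers yield
    ``None`` (either no solution or infinitely many; both are useless here).
    """
    dx = c1[0] - c0[0]
    dy = c1[1] - c0[1]
    d = math.hypot(dx, dy)
    if d <= _EPS:
        return None
    if d > r0 + r1 + _EPS or d < abs(r0 - r1) - _EPS:
        return None
    a = (d * d + r0 * r0 - r1 * r1) / (2.0 * d)
    h2 = r0 * r0 - a * a
    h = math.sqrt(h2) if h2 > 0.0 else 0.0
    ux, uy = dx / d, dy / d
    mx, my = c0[0] + a * ux, c0[1] + a * uy
    return ((mx - h * uy, my + h * ux), (mx + h * uy, my - h * ux))


def rotate_about(p, pivot, angle):
    """Rotate point ``p`` about ``pivot`` by ``angle`` radians (counterclockwise)."""
    c, s = math.cos(angle), math.sin(angle)
    dx, dy = p[0] - pivot[0], p[1] - pivot[1]
    return (pivot[0] + c * dx - s * dy, pivot[1] + s * dx + c * dy)


def interior_angle(a, b, c):
    """Interior angle at vertex ``b`` between segments (a,b) and (b,c), in radians.

    pi means the three points are collinear with ``b`` between ``a`` and ``c``
    (a straight junction); small values mean a sharp fold.
    """
    v1x, v1y = a[0] - b[0], a[1] - b[1]
    v2x, v2y = c[0] - b[0], c[1] - b[1]
    n1 = math.hypot(v1x, v1y)
    n2 = math.hypot(v2x, v2y)
    if n1 <= _EPS or n2 <= _EPS:
        raise ValueError("degenerate segment at angle vertex")
    cosang = (v1x * v2x + v1y * v2y) / (n1 * n2)
    return math.acos(min(1.0, max(-1.0, cosang)))


def _point_to_segments(px, py, ax, ay, bx, by):
    """Distance from one point to many segments (vectorized over segments)."""
    dx = bx - ax
    dy = by - ay
    len2 = dx * dx + dy * dy
    # degenerate segments collapse to their first endpoint
    t = np.where(len2 > 0.0, ((px - ax) * dx + (py - ay) * dy) / np.where(len2 > 0.0, len2, 1.0), 0.0)
    t = np.clip(t, 0.0, 1.0)
    cx = ax + t * dx
    cy = ay + t * dy
    return np.hypot(px - cx, py - cy)


def _points_to_segment(px, py, ax, ay, bx, by):
    """Distance from many points to one segment."""
    dx = bx - ax
    dy = by - ay
    len2 = dx * dx + dy * dy
    if len2 <= 0.0:
        return np.hypot(px - ax, py - ay)
    t = np.clip(((px - ax) * dx + (py - ay) * dy) / len2, 0.0, 1.0)
    return np.hypot(px - (ax + t * dx), py - (ay + t * dy))


def segment_to_segments_distance(p, q, a, b):
    """Minimum distance between segment (p, q) and each segment (a[i], b[i]).

    ``a``, ``b`` are ``(m, 2)`` arrays. Properly crossing pairs get distance 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim == 1:
        a = a[None, :]
        b = b[None, :]
    ax, ay = a[:, 0], a[:, 1]
    bx, by = b[:, 0], b[:, 1]
    px, py = float(p[0]), float(p[1])
    qx, qy = float(q[0]), float(q[1])

    d = np.minimum(
        np.minimum(
            _point_to_segments(px, py, ax, ay, bx, by),
            _point_to_segments(qx, qy, ax, ay, bx, by),
        ),
        np.minimum(
            _points_to_segment(ax, ay, px, py, qx, qy),
            _points_to_segment(bx, by, px, py, qx, qy),
        ),
    )

    # zero out properly intersecting pairs (orientation sign test)
    rx, ry = qx - px, qy - py
    d1 = rx * (ay - py) - ry * (ax - px)
    d2 = rx * (by - py) - ry * (bx - px)
    sx = bx - ax
    sy = by - ay
    d3 = sx * (py - ay) - sy * (px - ax)
    d4 = sx * (qy - ay) - sy * (qx - ax)
    crossing = (d1 * d2 < 0.0) & (d3 * d4 < 0.0)
    d[crossing] = 0.0
    return d


def axial_difference_deg(theta1, theta2):
    """Smallest angle between two axial (mod-180) orientations, in degrees, in [0, 90].

    Works elementwise on arrays.
    """
    d = np.abs(np.asarray(theta1, dtype=float) - np.asarray(theta2, dtype=float)) % 180.0
    return np.minimum(d, 180.0 - d)
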