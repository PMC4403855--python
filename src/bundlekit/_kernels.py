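"""Compiled inner loops for the filament overlap tests.

The per-step clearance check is the hot path of the simulator: every candidate
event must verify that the moved segments stay at least ``w`` away from every
non-adjacent cell segment. These kernels do that scan with an early bounding-box
reject and early exit on the first violation.
"""

from __future__ import annotations

import numba
import numpy as np


@numba.njit(cache=True, fastmath=False)
def seg_seg_dist(px, py, qx, qy, ax, ay, bx, by):
    """Minimum distance between segments (p,q) and (a,b)."""
    rx = qx - px
    ry = qy - py
    sx = bx - ax
    sy = by - ay
    # proper crossing test
    d1 = rx * (ay - py) - ry * (ax - px)
    d2 = rx * (by - py) - ry * (bx - px)
    d3 = sx * (py - ay) - sy * (px - ax)
    d4 = sx * (qy - ay) - sy * (qx - ax)
    if d1 * d2 < 0.0 and d3 * d4 < 0.0:
        return 0.0

    best = 1e300
    # p and q onto (a,b)
    len2 = sx * sx + sy * sy
    for (cx, cy) in ((px, py), (qx, qy)):
        if len2 > 0.0:
            t = ((cx - ax) * sx + (cy - ay) * sy) / len2
            if t < 0.0:
                t = 0.0
            elif t > 1.0:
                t = 1.0
        else:
            t = 0.0
        dx = cx - (ax + t * sx)
        dy = cy - (ay + t * sy)
        d = dx * dx + dy * dy
        if d < best:
            best = d
    # a and b onto (p,q)
    len2 = rx * rx + ry * ry
    for (cx, cy) in ((ax, ay), (bx, by)):
        if len2 > 0.0:
            t = ((cx - px) * rx + (cy - py) * ry) / len2
            if t < 0.0:
                t = 0.0
            elif t > 1.0:
                t = 1.0
        else:
            t = 0.0
        dx = cx - (px + t * rx)
        dy = cy - (py + t * ry)
        d = dx * dx + dy * dy
        if d < best:
            best = d
    return np.sqrt(best)


@numba.njit(cache=True, fastmath=False)
def clearance_ok(nodes, n_nodes, px, py, qx, qy, skip_lo, skip_hi, extra1, extra2, w):
    """True when segment (p,q) keeps distance >= w from every cell segment,
    skipping cell indices in [skip_lo, skip_hi] and the two extra indices.

    ``nodes`` is the (capacity, 2) node array; cell i spans nodes i, i+1.
    """
    bxmin = min(px, qx) - w
    bxmax = max(px, qx) + w
    bymin = min(py, qy) - w
    bymax = max(py, qy) + w
    n_cells = n_nodes - 1
    for i in range(n_cells):
        if skip_lo <= i <= skip_hi or i == extra1 or i == extra2:
            continue
        ax = nodes[i, 0]
        ay = nodes[i, 1]
        bx = nodes[i + 1, 0]
        by = nodes[i + 1, 1]
        # bounding-box reject
        if (ax < bxmin and bx < bxmin) or (ax > bxmax and bx > bxmax):
            continue
        if (ay < bymin and by < bymin) or (ay > bymax and by > bymax):
            continue
        if seg_seg_dist(px, py, qx, qy, ax, ay, bx, by) < w:
            return False
    return True
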