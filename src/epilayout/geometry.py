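"""Pure 2-D geometry kernel.

Coordinates are millimetres throughout: ``u`` across the forearm width
(positive toward the radial side), ``v`` along the forearm (positive toward
the elbow).  Polygons are simple, implicitly closed vertex lists.

The convex-hull area (Graham scan + shoelace) and the point-in-polygon test
(ray casting with explicit boundary handling) are implemented here rather
than delegated, because the layout scoring and validity rules are defined
directly in terms of these primitives.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .errors import DegenerateGeometryError

__all__ = [
    "convex_hull",
    "convex_hull_area",
    "point_in_polygon",
    "point_segment_distance",
    "point_polygon_distance",
    "pair_angle_to_line",
    "polygon_area",
]

_EPS = 1e-9


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise DegenerateGeometryError(f"expected an (n, 2) point array, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise DegenerateGeometryError("non-finite coordinates")
    return pts


def _cross(o, a, b) -> float:
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def convex_hull(points: Sequence) -> np.ndarray:
    """Convex hull vertices in counter-clockwise order (Graham scan).

    Raises :class:`DegenerateGeometryError` for fewer than 3 distinct points
    or an all-collinear set.
    """
    pts = np.unique(_as_points(points), axis=0)
    if len(pts) < 3:
        raise DegenerateGeometryError("convex hull needs at least 3 distinct points")
    # pivot: lowest v, then lowest u
    pivot_idx = np.lexsort((pts[:, 0], pts[:, 1]))[0]
    pivot = pts[pivot_idx]
    rest = np.delete(pts, pivot_idx, axis=0)
    angles = np.arctan2(rest[:, 1] - pivot[1], rest[:, 0] - pivot[0])
    dists = np.hypot(rest[:, 0] - pivot[0], rest[:, 1] - pivot[1])
    order = np.lexsort((dists, angles))
    stack = [pivot]
    for p in rest[order]:
        while len(stack) >= 2 and _cross(stack[-2], stack[-1], p) <= _EPS:
            stack.pop()
        stack.append(p)
    if len(stack) < 3:
        raise DegenerateGeometryError("all points are collinear")
    return np.array(stack)


def polygon_area(vertices: Sequence) -> float:
    """Signed-area magnitude of a simple polygon (shoelace formula)."""
    verts = _as_points(vertices)
    x, y = verts[:, 0], verts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def convex_hull_area(points: Sequence) -> float:
    """Area (mm^2) of the convex hull of ``points``, via Graham scan."""
    return polygon_area(convex_hull(points))


def point_segment_distance(p, a, b) -> float:
    """Euclidean distance from point ``p`` to the closed segment ``ab``."""
    p = np.asarray(p, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ab = b - a
    denom = float(ab @ ab)
    if denom < _EPS * _EPS:
        raise DegenerateGeometryError("degenerate segment: a == b")
    t = float((p - a) @ ab) / denom
    t = min(1.0, max(0.0, t))
    return float(np.hypot(*(p - (a + t * ab))))


def point_in_polygon(p, polygon: Sequence, tol: float = _EPS) -> bool:
    """True iff ``p`` is strictly inside ``polygon`` or on its boundary.

    Ray casting (even-odd rule) with an explicit boundary pre-check so that
    points on an edge or vertex count as inside.
    """
    verts = _as_points(polygon)
    if len(verts) < 3:
        raise DegenerateGeometryError("polygon needs at least 3 vertices")
    px, py = float(p[0]), float(p[1])
    n = len(verts)
    for i in range(n):
        a, b = verts[i], verts[(i + 1) % n]
        if np.hypot(*(b - a)) < _EPS:
            continue
        if point_segment_distance((px, py), a, b) <= tol:
            return True
    inside = False
    for i in range(n):
        (ax, ay), (bx, by) = verts[i], verts[(i + 1) % n]
        if (ay > py) != (by > py):
            x_int = ax + (py - ay) * (bx - ax) / (by - ay)
            if px < x_int:
                inside = not inside
    return inside


def point_polygon_distance(p, polygon: Sequence) -> float:
    """Distance from ``p`` to a polygon; 0 if inside or on the boundary."""
    if point_in_polygon(p, polygon):
        return 0.0
    verts = _as_points(polygon)
    n = len(verts)
    return min(
        point_segment_distance(p, verts[i], verts[(i + 1) % n])
        for i in range(n)
        if np.hypot(*(verts[(i + 1) % n] - verts[i])) >= _EPS
    )


def pair_angle_to_line(e1, e2, k1, k2) -> float:
    """Axial angle, in degrees within [0, 90], between an electrode pair and
    a muscle line.

    The bipolar pair ``(e1, e2)`` is unordered and has no orientation sign,
    so the arccos of the *absolute* normalized dot product is used: parallel
    and antiparallel both give 0 deg, perpendicular gives 90 deg.
    """
    e = np.asarray(e2, dtype=float) - np.asarray(e1, dtype=float)
    k = np.asarray(k2, dtype=float) - np.asarray(k1, dtype=float)
    ne, nk = np.hypot(*e), np.hypot(*k)
    if ne < _EPS or nk < _EPS:
        raise DegenerateGeometryError("zero-length vector in angle computation")
    c = abs(float(e @ k)) / (ne * nk)
    return math.degrees(math.acos(min(1.0, c)))
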