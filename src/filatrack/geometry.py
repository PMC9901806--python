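"""Shared raster geometry helpers.

Coordinate convention used across the package: a point is ``(x, y)`` with
``x`` = column and ``y`` = row; image arrays are indexed ``array[y, x]``.
Angles are measured in degrees from the +x axis, counter-clockwise in
display space (y pointing down), i.e. the direction vector of an angle
``theta`` is ``(cos(theta), -sin(theta))``.  Orientations (undirected
angles) live in ``[0, 180)``.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = [
    "direction_vector",
    "orientation_of",
    "normalize_orientation",
    "orientation_difference",
    "ray_points",
    "bresenham_line",
    "polyline_length",
    "disk_offsets",
    "stamp_disks",
]


def direction_vector(angle_deg: float) -> np.ndarray:
    """Unit direction ``(dx, dy)`` of ``angle_deg`` in display space."""
    rad = np.deg2rad(angle_deg)
    return np.array([np.cos(rad), -np.sin(rad)])


def normalize_orientation(angle_deg: float) -> float:
    """Map any angle (degrees) to an undirected orientation in [0, 180)."""
    return float(np.mod(angle_deg, 180.0))


def orientation_of(dx: float, dy: float) -> float:
    """Orientation in [0, 180) of the vector ``(dx, dy)``."""
    if dx == 0 and dy == 0:
        raise ValueError("zero vector has no orientation")
    return normalize_orientation(np.rad2deg(np.arctan2(-dy, dx)))


def orientation_difference(a: float, b: float) -> float:
    """Undirected angular difference between two orientations, in [0, 90]."""
    d = abs(normalize_orientation(a) - normalize_orientation(b))
    return min(d, 180.0 - d)


def ray_points(start, angle_deg: float, length: int) -> np.ndarray:
    """Integer sample points along a ray.

    Returns ``length`` points at unit spacing starting one step after
    ``start`` (the start pixel itself is excluded).  Points may fall
    outside the image; callers decide how to treat them.
    """
    x0, y0 = start
    d = direction_vector(angle_deg)
    t = np.arange(1, int(length) + 1, dtype=float)
    pts = np.stack([x0 + t * d[0], y0 + t * d[1]], axis=1)
    return np.rint(pts).astype(int)


def bresenham_line(p0, p1) -> np.ndarray:
    """Integer pixel chain from ``p0`` to ``p1`` inclusive (8-connected)."""
    x0, y0 = int(p0[0]), int(p0[1])
    x1, y1 = int(p1[0]), int(p1[1])
    n = max(abs(x1 - x0), abs(y1 - y0))
    if n == 0:
        return np.array([[x0, y0]], dtype=int)
    t = np.linspace(0.0, 1.0, n + 1)
    xs = np.rint(x0 + t * (x1 - x0)).astype(int)
    ys = np.rint(y0 + t * (y1 - y0)).astype(int)
    pts = np.stack([xs, ys], axis=1)
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.any(np.diff(pts, axis=0) != 0, axis=1)
    return pts[keep]


def polyline_length(points) -> float:
    """Sum of Euclidean distances between consecutive points."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


@lru_cache(maxsize=256)
def disk_offsets(diameter: int) -> tuple:
    """Integer offsets of a rasterized disk of given diameter.

    A disk of diameter ``d`` centered on a pixel contains all pixels whose
    center distance is at most ``d / 2``.
    """
    if diameter < 1:
        return ((np.zeros(0, dtype=int), np.zeros(0, dtype=int)))
    r = diameter / 2.0
    ri = int(np.floor(r))
    dy, dx = np.mgrid[-ri : ri + 1, -ri : ri + 1]
    inside = dx * dx + dy * dy <= r * r + 1e-9
    return (dx[inside].copy(), dy[inside].copy())


def stamp_disks(shape, points, diameters) -> np.ndarray:
    """Boolean mask of disks of per-point ``diameters`` stamped at ``points``."""
    h, w = shape
    out = np.zeros(shape, dtype=bool)
    pts = np.asarray(points, dtype=int)
    dias = np.broadcast_to(np.asarray(diameters, dtype=int), (len(pts),))
    for (x, y), d in zip(pts, dias):
        dx, dy = disk_offsets(max(int(d), 1))
        xs = x + dx
        ys = y + dy
        ok = (xs >= 0) & (xs < w) & (ys >= 0) & (ys < h)
        out[ys[ok], xs[ok]] = True
    return out
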