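"""Width map, orientation field and straight-line filament sensing.

The width map stores, for every foreground pixel, the largest disk
diameter centered there whose miss fraction (disk pixels falling on
background or outside the image) does not exceed the tolerance.  The
diameter is increased until the condition first fails.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .filament import Filament
from .geometry import direction_vector, disk_offsets, ray_points

__all__ = [
    "WidthMap",
    "OrientationField",
    "SensorSettings",
    "compute_width_map",
    "threshold_width_map",
    "directional_mean_width",
    "scan_straight_filaments",
]


@dataclass
class SensorSettings:
    minimal_length: float = 30.0  # pixels
    tolerance: float = 0.0  # max fraction of disk misses
    angle_increment: float = 3.0  # degrees, straight-mode probing step

    def __post_init__(self):
        if self.minimal_length < 2:
            raise ValueError("minimal_length must be >= 2")
        if not (0.0 <= self.tolerance <= 1.0):
            raise ValueError("tolerance must be in [0, 1]")
        if self.angle_increment <= 0:
            raise ValueError("angle_increment must be positive")


@dataclass
class WidthMap:
    diameters: np.ndarray  # (H, W) int; 0 on background
    tolerance: float = 0.0

    @property
    def shape(self):
        return self.diameters.shape

    def value_at(self, point) -> float:
        """Width at an (x, y) point; 0 off-image."""
        x, y = int(point[0]), int(point[1])
        h, w = self.diameters.shape
        if 0 <= x < w and 0 <= y < h:
            return float(self.diameters[y, x])
        return 0.0


class OrientationField:
    """Per-pixel orientation marks of accepted filaments; NaN = unset.

    Earlier (longer) filaments take priority: marking never overwrites an
    already-set pixel.
    """

    def __init__(self, shape):
        self.angle = np.full(shape, np.nan)

    @property
    def shape(self):
        return self.angle.shape

    def is_set(self) -> np.ndarray:
        return ~np.isnan(self.angle)

    def mark(self, mask: np.ndarray, orientation: float) -> None:
        target = mask & np.isnan(self.angle)
        self.angle[target] = float(orientation) % 180.0

    def values_at(self, points) -> np.ndarray:
        """Field values at (x, y) points; NaN off-image or unset."""
        pts = np.asarray(points, dtype=int)
        h, w = self.angle.shape
        out = np.full(len(pts), np.nan)
        ok = (pts[:, 0] >= 0) & (pts[:, 0] < w) & (pts[:, 1] >= 0) & (pts[:, 1] < h)
        out[ok] = self.angle[pts[ok, 1], pts[ok, 0]]
        return out


def compute_width_map(mask: np.ndarray, tolerance: float = 0.0) -> WidthMap:
    """Grow a disk at every foreground pixel until the miss fraction
    exceeds ``tolerance``; store the last diameter that still fit."""
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2 or mask.size == 0:
        raise ValueError("mask must be a non-empty 2D array")
    if not (0.0 <= tolerance <= 1.0):
        raise ValueError("tolerance must be in [0, 1]")
    h, w = mask.shape
    diameters = np.zeros(mask.shape, dtype=int)
    alive = mask.copy()
    m = mask.astype(np.int32)
    d = 1
    max_d = int(np.hypot(h, w)) + 2
    while alive.any() and d <= max_d:
        dx, dy = disk_offsets(d)
        total = len(dx)
        kernel = np.zeros((2 * max(abs(dy.min()), dy.max(), 0) + 1,
                           2 * max(abs(dx.min()), dx.max(), 0) + 1), dtype=np.int32)
        kernel[dy + kernel.shape[0] // 2, dx + kernel.shape[1] // 2] = 1
        hits = ndimage.convolve(m, kernel, mode="constant", cval=0)
        misses = total - hits
        passing = misses <= tolerance * total + 1e-9
        alive &= passing
        diameters[alive] = d
        d += 1
    return WidthMap(diameters=diameters, tolerance=float(tolerance))


def threshold_width_map(wm: WidthMap, current_diameter: int) -> np.ndarray:
    """Foreground exactly where diameters >= current_diameter."""
    if current_diameter < 1:
        raise ValueError("current_diameter must be >= 1")
    return wm.diameters > (current_diameter - 1)


def directional_mean_width(wm: WidthMap, start, angle_deg: float, length: int) -> float:
    """Mean width-map value along a rasterized ray of ``length`` samples
    from ``start`` (exclusive); off-image samples count as width 0."""
    if length < 1:
        raise ValueError("length must be >= 1")
    pts = ray_points(start, angle_deg, length)
    h, w = wm.diameters.shape
    ok = (pts[:, 0] >= 0) & (pts[:, 0] < w) & (pts[:, 1] >= 0) & (pts[:, 1] < h)
    vals = np.zeros(len(pts))
    vals[ok] = wm.diameters[pts[ok, 1], pts[ok, 0]]
    return float(vals.mean())


# ---------------------------------------------------------------------------
# straight-line sensing


def _walk_straight(wm: WidthMap, start, angle_deg: float) -> list:
    """Walk from ``start`` (exclusive) in a fixed direction while the
    pointwise width stays >= 1; returns the visited pixels."""
    h, w = wm.diameters.shape
    d = direction_vector(angle_deg)
    out = []
    t = 1
    last = (int(start[0]), int(start[1]))
    while True:
        x = int(round(start[0] + t * d[0]))
        y = int(round(start[1] + t * d[1]))
        t += 1
        if (x, y) == last:
            continue
        if not (0 <= x < w and 0 <= y < h) or wm.diameters[y, x] < 1:
            return out
        out.append((x, y))
        last = (x, y)


def _best_straight_line(wm: WidthMap, seed, increment: float):
    """Longest straight run through ``seed``; ties broken by smaller angle."""
    best = None
    n = int(round(180.0 / increment))
    for k in range(n):
        theta = k * increment
        fwd = _walk_straight(wm, seed, theta)
        bwd = _walk_straight(wm, seed, theta + 180.0)
        chain = list(reversed(bwd)) + [tuple(int(v) for v in seed)] + fwd
        p0, p1 = np.array(chain[0]), np.array(chain[-1])
        length = float(np.linalg.norm(p1 - p0))
        if best is None or length > best[0] + 1e-9:
            best = (length, theta, chain)
    return best


def scan_straight_filaments(wm: WidthMap, s: SensorSettings):
    """Detect straight filaments on the width map, longest first.

    Seeds are processed in decreasing width order; pixels covered by an
    already-found candidate do not seed again.  Accepted filaments claim
    their pixels (longest first) and mark the orientation field.
    """
    h, w = wm.diameters.shape
    ys, xs = np.nonzero(wm.diameters)
    if len(xs) == 0:
        return [], OrientationField((h, w))
    order = np.lexsort((xs, ys, -wm.diameters[ys, xs]))
    covered = np.zeros((h, w), dtype=bool)
    candidates = []
    for i in order:
        x, y = int(xs[i]), int(ys[i])
        if covered[y, x]:
            continue
        length, theta, chain = _best_straight_line(wm, (x, y), s.angle_increment)
        if length < s.minimal_length or len(chain) < 2:
            continue
        pts = np.asarray(chain, dtype=int)
        widths = wm.diameters[pts[:, 1], pts[:, 0]].astype(float)
        f = Filament(
            chain=pts,
            widths=widths,
            vertex_idx=np.array([0, len(pts) - 1]),
            score=float(widths.sum()),
        )
        candidates.append(f)
        covered |= f.coverage_mask((h, w))

    candidates.sort(
        key=lambda f: (-f.length, f.chain[0][1], f.chain[0][0])
    )
    field = OrientationField((h, w))
    accepted = []
    claimed = np.zeros((h, w), dtype=bool)
    for f in candidates:
        # pixels claimed by a longer filament are not re-used; a candidate
        # must still contribute minimal_length of unclaimed length
        on_claimed = claimed[f.chain[:, 1], f.chain[:, 0]].mean() if accepted else 0.0
        if f.length * (1.0 - on_claimed) < s.minimal_length:
            continue
        pix = f.coverage_mask((h, w))
        claimed |= pix
        field.mark(pix, f.piece_orientations()[0])
        f.id = len(accepted)
        accepted.append(f)
    return accepted, field
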