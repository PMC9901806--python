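"""Ground-truthed synthetic images, stacks and blob movies.

Truth tables are produced from the analytic stroke definitions before
rasterization, never measured back from pixels, so they can serve as
independent oracles for the detection and tracking modules.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .geometry import orientation_of, stamp_disks

__all__ = [
    "StrokeSpec",
    "line_stroke",
    "arc_stroke",
    "bezier_stroke",
    "render_strokes",
    "render_stroke_movie",
    "stroke_polyline",
    "static_blob_movie",
    "split_blob_movie",
    "merge_blob_movie",
    "touch_blob_movie",
]

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(48)


@dataclass(frozen=True)
class StrokeSpec:
    """A drawable stroke (line, circular arc or quadratic Bézier) with
    closed-form ground truth."""

    kind: str  # 'line' | 'arc' | 'bezier'
    params: tuple  # kind-specific geometry, see constructors below
    width: int = 4
    intensity: int = 200

    # -- geometry ---------------------------------------------------------

    def point(self, t):
        t = np.asarray(t, dtype=float)
        if self.kind == "line":
            (x0, y0), (x1, y1) = self.params
            return np.stack([x0 + t * (x1 - x0), y0 + t * (y1 - y0)], axis=-1)
        if self.kind == "arc":
            (cx, cy), r, th0, th1 = self.params
            th = th0 + t * (th1 - th0)
            return np.stack([cx + r * np.cos(th), cy + r * np.sin(th)], axis=-1)
        if self.kind == "bezier":
            p0, p1, p2 = (np.asarray(p, dtype=float) for p in self.params)
            t = t[..., None]
            return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2
        raise ValueError(f"unknown stroke kind {self.kind!r}")

    def _speed(self, t):
        t = np.asarray(t, dtype=float)
        if self.kind == "line":
            (x0, y0), (x1, y1) = self.params
            return np.full(t.shape, np.hypot(x1 - x0, y1 - y0))
        if self.kind == "arc":
            _, r, th0, th1 = self.params
            return np.full(t.shape, abs(th1 - th0) * r)
        p0, p1, p2 = (np.asarray(p, dtype=float) for p in self.params)
        d = 2 * (1 - t[..., None]) * (p1 - p0) + 2 * t[..., None] * (p2 - p1)
        return np.linalg.norm(d, axis=-1)

    def arc_length(self) -> float:
        """Closed form for lines/arcs; Gauss-Legendre quadrature for Béziers."""
        if self.kind == "line":
            (x0, y0), (x1, y1) = self.params
            return float(np.hypot(x1 - x0, y1 - y0))
        if self.kind == "arc":
            _, r, th0, th1 = self.params
            return float(r * abs(th1 - th0))
        t = 0.5 * (_GL_NODES + 1.0)
        return float(0.5 * np.sum(_GL_WEIGHTS * self._speed(t)))

    def mean_curvature(self) -> float:
        """Arc-length-averaged absolute curvature (1/R for arcs)."""
        if self.kind == "line":
            return 0.0
        if self.kind == "arc":
            _, r, _, _ = self.params
            return 1.0 / r
        p0, p1, p2 = (np.asarray(p, dtype=float) for p in self.params)
        t = 0.5 * (_GL_NODES + 1.0)
        d1 = 2 * (1 - t[:, None]) * (p1 - p0) + 2 * t[:, None] * (p2 - p1)
        d2 = 2 * (p2 - 2 * p1 + p0)
        cross = np.abs(d1[:, 0] * d2[1] - d1[:, 1] * d2[0])
        speed = np.linalg.norm(d1, axis=1)
        total_turn = 0.5 * np.sum(_GL_WEIGHTS * cross / speed**2)
        return float(total_turn / self.arc_length())

    def chord_angle(self) -> float:
        a, b = self.point(0.0), self.point(1.0)
        d = b - a
        return orientation_of(d[0], d[1])

    def translated(self, dx: float, dy: float) -> "StrokeSpec":
        off = np.array([dx, dy])
        if self.kind == "line":
            (p0, p1) = self.params
            return replace(self, params=(tuple(np.add(p0, off)), tuple(np.add(p1, off))))
        if self.kind == "arc":
            c, r, th0, th1 = self.params
            return replace(self, params=(tuple(np.add(c, off)), r, th0, th1))
        p0, p1, p2 = self.params
        return replace(
            self,
            params=(tuple(np.add(p0, off)), tuple(np.add(p1, off)), tuple(np.add(p2, off))),
        )


def line_stroke(p0, p1, width=4, intensity=200) -> StrokeSpec:
    return StrokeSpec("line", (tuple(p0), tuple(p1)), width, intensity)


def arc_stroke(center, radius, theta0, theta1, width=4, intensity=200) -> StrokeSpec:
    return StrokeSpec("arc", (tuple(center), float(radius), float(theta0), float(theta1)), width, intensity)


def bezier_stroke(p0, p1, p2, width=4, intensity=200) -> StrokeSpec:
    return StrokeSpec("bezier", (tuple(p0), tuple(p1), tuple(p2)), width, intensity)


def stroke_polyline(spec: StrokeSpec, n_points: int = 33) -> np.ndarray:
    """Integer polyline sampled uniformly in parameter along the stroke."""
    return np.rint(spec.point(np.linspace(0.0, 1.0, n_points))).astype(int)


def truth_table(specs) -> pd.DataFrame:
    rows = []
    for i, sp in enumerate(specs):
        rows.append(
            {
                "id": i,
                "kind": sp.kind,
                "length": sp.arc_length(),
                "width": sp.width,
                "angle": sp.chord_angle(),
                "curvature": sp.mean_curvature(),
            }
        )
    return pd.DataFrame(rows, columns=["id", "kind", "length", "width", "angle", "curvature"])


def render_strokes(
    specs,
    shape=(512, 512),
    noise_sigma: float = 0.0,
    seed: int = 0,
    background: int = 10,
):
    """Rasterize strokes onto an 8-bit canvas; returns (image, truth).

    The stroke footprint is the densely sampled centerline dilated by a
    disk of the stroke width; noise is additive Gaussian clipped to the
    dtype.  A fixed seed reproduces the image bit-identically.
    """
    h, w = shape
    canvas = np.full(shape, background, dtype=float)
    for sp in specs:
        n = max(int(np.ceil(4 * sp.arc_length())), 2)
        pts = np.rint(sp.point(np.linspace(0.0, 1.0, n))).astype(int)
        if (
            pts[:, 0].min() < 0
            or pts[:, 1].min() < 0
            or pts[:, 0].max() >= w
            or pts[:, 1].max() >= h
        ):
            raise ValueError("stroke outside canvas")
        mask = stamp_disks(shape, pts, sp.width)
        canvas[mask] = sp.intensity
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        canvas = canvas + rng.normal(0.0, noise_sigma, size=shape)
    return np.clip(canvas, 0, 255).astype(np.uint8), truth_table(specs)


def render_stroke_movie(
    specs,
    n_frames: int,
    drift=(3.0, 0.0),
    shape=(512, 512),
    noise_sigma: float = 0.0,
    seed: int = 0,
    extras=None,
):
    """Time-lapse of rigidly drifting strokes.

    ``extras`` maps a frame index to additional strokes present only in
    that frame (for single-frame noise fixtures).  Returns the uint8
    stack, per-frame truth tables, and per-frame stroke spec lists.
    """
    stack = []
    truths = []
    per_frame_specs = []
    for t in range(n_frames):
        frame_specs = [sp.translated(t * drift[0], t * drift[1]) for sp in specs]
        if extras and t in extras:
            frame_specs = frame_specs + list(extras[t])
        img, truth = render_strokes(
            frame_specs, shape=shape, noise_sigma=noise_sigma, seed=seed + t
        )
        truth.insert(0, "frame", t)
        stack.append(img)
        truths.append(truth)
        per_frame_specs.append(frame_specs)
    return np.stack(stack), pd.concat(truths, ignore_index=True), per_frame_specs


# ---------------------------------------------------------------------------
# blob movies (scripted cell-event oracles)


def _blob_frame(shape, circles) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for (cx, cy), r in circles:
        mask |= stamp_disks(shape, [(int(cx), int(cy))], int(2 * r + 1))
    return mask


def static_blob_movie(n_frames: int = 4, shape=(80, 120)):
    """One stationary blob; truth: a single lifeline spanning all frames."""
    frames = [_blob_frame(shape, [((40, 40), 12)]) for _ in range(n_frames)]
    return np.stack(frames), []


def split_blob_movie(n_frames: int = 8, split_frame: int = 4, shape=(80, 160)):
    """One blob that divides at ``split_frame`` and keeps separating."""
    frames = []
    for t in range(n_frames):
        if t < split_frame:
            circles = [((60, 40), 12)]
        else:
            off = 14 + 8 * (t - split_frame)
            circles = [((60 - off, 40), 12), ((60 + off, 40), 12)]
        frames.append(_blob_frame(shape, circles))
    return np.stack(frames), [("split", split_frame)]


def merge_blob_movie(n_frames: int = 7, merge_frame: int = 3, shape=(80, 160)):
    """Two blobs that approach and stay merged to the end of the stack."""
    xa = {0: 20, 1: 33, 2: 46}
    xb = {0: 120, 1: 107, 2: 94}
    frames = []
    for t in range(n_frames):
        if t < merge_frame:
            circles = [((xa.get(t, 46), 40), 12), ((xb.get(t, 94), 40), 12)]
        else:
            circles = [((60, 40), 12), ((78, 40), 12)]  # overlapping -> one area
        frames.append(_blob_frame(shape, circles))
    return np.stack(frames), [("fusion", merge_frame)]


def touch_blob_movie(
    n_frames: int = 9, touch_frame: int = 3, detouch_frame: int = 6, shape=(80, 160)
):
    """Two blobs that merge at ``touch_frame`` and separate again at
    ``detouch_frame``; truth events are Touch and DeTouch."""
    if not (0 < touch_frame < detouch_frame < n_frames):
        raise ValueError("need 0 < touch_frame < detouch_frame < n_frames")
    frames = []
    for t in range(n_frames):
        if t < touch_frame:
            gap = 40 + 16 * (touch_frame - 1 - t)
        elif t < detouch_frame:
            gap = 18  # overlapping -> one 8-connected area
        else:
            gap = 40 + 16 * (t - detouch_frame)
        xa, xb = 70 - gap // 2, 70 + gap // 2
        frames.append(_blob_frame(shape, [((xa, 40), 12), ((xb, 40), 12)]))
    return np.stack(frames), [("touch", touch_frame), ("detouch", detouch_frame)]
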