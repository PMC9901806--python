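"""Per-filament and per-cell descriptors, order parameter and the
pixel-wise / object-wise detection comparison operators."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure

from .filament import Filament
from .geometry import orientation_of, polyline_length

__all__ = [
    "FilamentRecord",
    "CellRecord",
    "filament_descriptors",
    "order_parameter",
    "cell_shape_descriptors",
    "compare_pixelwise",
    "compare_objectwise",
    "records_to_frame",
    "frame_summary",
]


@dataclass
class FilamentRecord:
    id: int
    center_x: float
    center_y: float
    length: float  # pixels
    width: float  # mean disk diameter, pixels
    angle: float  # degrees in [0, 180)
    curvature: float  # 1/pixels

    def as_dict(self) -> dict:
        return {
            "id": self.id,
            "center_x": self.center_x,
            "center_y": self.center_y,
            "length": self.length,
            "width": self.width,
            "angle": self.angle,
            "curvature": self.curvature,
        }


@dataclass
class CellRecord:
    area: float  # pixels^2
    center_x: float
    center_y: float
    long_half_axis: float
    short_half_axis: float
    aspect_ratio: float
    mean_brightness: float
    contour: np.ndarray  # (N, 2) closed polygon, (x, y)

    def as_dict(self) -> dict:
        return {
            "area": self.area,
            "center_x": self.center_x,
            "center_y": self.center_y,
            "long_half_axis": self.long_half_axis,
            "short_half_axis": self.short_half_axis,
            "aspect_ratio": self.aspect_ratio,
            "mean_brightness": self.mean_brightness,
        }


def _turning_curvature(points: np.ndarray, length: float) -> float:
    """Total absolute turning angle (radians) at interior vertices divided
    by the polyline length; converges to 1/R on circular arcs."""
    if len(points) < 3 or length <= 0:
        return 0.0
    v = np.diff(np.asarray(points, dtype=float), axis=0)
    ang = np.arctan2(v[:, 1], v[:, 0])
    turn = np.diff(ang)
    turn = np.mod(turn + np.pi, 2 * np.pi) - np.pi
    return float(np.sum(np.abs(turn)) / length)


def filament_descriptors(
    f: Filament, img: np.ndarray | None = None, angle_mode: str = "chord"
) -> FilamentRecord:
    """Descriptors of one filament.

    length: sum of Euclidean distances of consecutive polyline points;
    width: mean of per-point widths; angle: endpoint-chord orientation
    (``angle_mode='mean'`` uses the length-weighted circular mean of piece
    orientations instead); curvature: total |turning angle| / length.
    """
    pts = f.points.astype(float)
    length = polyline_length(pts)
    center = pts.mean(axis=0)
    chord = pts[-1] - pts[0]
    if angle_mode == "chord" and (chord[0] != 0 or chord[1] != 0):
        angle = orientation_of(chord[0], chord[1])
    else:
        pieces = np.deg2rad(f.piece_orientations())
        lens = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        z = np.sum(lens * np.exp(2j * pieces))
        angle = float(np.mod(np.rad2deg(np.angle(z)) / 2.0, 180.0))
    return FilamentRecord(
        id=f.id if f.id is not None else -1,
        center_x=float(center[0]),
        center_y=float(center[1]),
        length=float(length),
        width=f.mean_width,
        angle=float(angle),
        curvature=_turning_curvature(pts, length),
    )


def order_parameter(records) -> float:
    """Length-weighted nematic order S = |sum l_k exp(2i theta_k)| / sum l_k."""
    if len(records) == 0:
        raise ValueError("order_parameter needs at least one record")
    lens = np.array([r.length for r in records], dtype=float)
    ang = np.deg2rad([r.angle for r in records])
    return float(np.abs(np.sum(lens * np.exp(2j * ang))) / np.sum(lens))


def cell_shape_descriptors(mask: np.ndarray, img: np.ndarray | None = None) -> CellRecord:
    """Shape/intensity descriptors of the largest connected foreground
    component: area, centroid, moment-based half axes, aspect ratio, mean
    brightness and the outer boundary polygon."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    lab = measure.label(mask, connectivity=2)
    props = measure.regionprops(
        lab, intensity_image=None if img is None else np.asarray(img, dtype=float)
    )
    p = max(props, key=lambda r: r.area)
    cy, cx = p.centroid
    long_half = p.axis_major_length / 2.0
    short_half = p.axis_minor_length / 2.0
    aspect = long_half / short_half if short_half > 0 else np.inf
    # pad so components touching the border still yield a closed contour
    padded = np.pad(lab == p.label, 1)
    contours = measure.find_contours(padded, 0.5)
    contour = max(contours, key=len)[:, ::-1] - 1.0  # (row, col) -> (x, y), unpad
    return CellRecord(
        area=float(p.area),
        center_x=float(cx),
        center_y=float(cy),
        long_half_axis=float(long_half),
        short_half_axis=float(short_half),
        aspect_ratio=float(aspect),
        mean_brightness=float(p.intensity_mean) if img is not None else float("nan"),
        contour=contour,
    )


def _pixel_sets(filaments, shape):
    return [
        {(int(x), int(y)) for x, y in zip(*np.nonzero(f.pixel_set(shape))[::-1])}
        for f in filaments
    ]


def compare_pixelwise(A, B, shape) -> dict:
    """Partition the union of rasterized filament pixels into only-A,
    only-B and both."""
    pa = set().union(*_pixel_sets(A, shape)) if A else set()
    pb = set().union(*_pixel_sets(B, shape)) if B else set()
    return {
        "only_A": len(pa - pb),
        "only_B": len(pb - pa),
        "both": len(pa & pb),
    }


def compare_objectwise(A, B, shape, match_fraction: float = 0.75) -> dict:
    """Greedy one-to-one matching of filaments as objects.

    ``a`` matches ``b`` iff |pixels(a) ∩ pixels(b)| / |pixels(a)| >=
    match_fraction; pairs are assigned in decreasing overlap order.
    """
    if not (0.0 < match_fraction <= 1.0):
        raise ValueError("match_fraction must be in (0, 1]")
    pa = _pixel_sets(A, shape)
    pb = _pixel_sets(B, shape)
    pairs = []
    for i, sa in enumerate(pa):
        for j, sb in enumerate(pb):
            ov = len(sa & sb)
            if len(sa) > 0 and ov / len(sa) >= match_fraction:
                pairs.append((ov, i, j))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a, used_b, matched = set(), set(), []
    for ov, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matched.append((i, j))
    return {
        "matched": matched,
        "only_A": sorted(set(range(len(A))) - used_a),
        "only_B": sorted(set(range(len(B))) - used_b),
    }


def records_to_frame(records) -> pd.DataFrame:
    """One CSV row per filament."""
    cols = ["id", "center_x", "center_y", "length", "width", "angle", "curvature"]
    return pd.DataFrame([r.as_dict() for r in records], columns=cols)


def frame_summary(records) -> dict:
    """Per-frame summary row: counts, means and the order parameter."""
    if len(records) == 0:
        return {
            "n_filaments": 0,
            "mean_length": float("nan"),
            "mean_width": float("nan"),
            "mean_curvature": float("nan"),
            "order_parameter": float("nan"),
        }
    return {
        "n_filaments": len(records),
        "mean_length": float(np.mean([r.length for r in records])),
        "mean_width": float(np.mean([r.width for r in records])),
        "mean_curvature": float(np.mean([r.curvature for r in records])),
        "order_parameter": order_parameter(records),
    }
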