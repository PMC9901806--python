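"""The Filament data structure shared by sensing, tracing and features."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    bresenham_line,
    orientation_of,
    polyline_length,
    stamp_disks,
)

__all__ = ["Filament"]


@dataclass
class Filament:
    """An ordered chain of raster pixels with per-pixel widths.

    ``chain`` holds every raster pixel of the traced path, ``widths`` the
    disk diameter of the width map at each pixel, and ``vertex_idx`` the
    indices into ``chain`` that delimit the consecutive straight pieces.
    The coarse polyline (``points``) consists of the chain pixels at the
    vertex indices; filament length is measured along that polyline.
    """

    chain: np.ndarray  # (N, 2) int, (x, y)
    widths: np.ndarray  # (N,) float
    vertex_idx: np.ndarray  # (K,) int, increasing; first 0, last N-1
    score: float = 0.0
    id: int | None = field(default=None, compare=False)

    def __post_init__(self):
        self.chain = np.asarray(self.chain, dtype=int)
        self.widths = np.asarray(self.widths, dtype=float)
        self.vertex_idx = np.asarray(self.vertex_idx, dtype=int)
        if len(self.chain) < 2:
            raise ValueError("a filament needs at least 2 points")
        if len(self.widths) != len(self.chain):
            raise ValueError("widths and chain length differ")
        if self.vertex_idx[0] != 0 or self.vertex_idx[-1] != len(self.chain) - 1:
            raise ValueError("vertex_idx must span the whole chain")

    # -- construction -----------------------------------------------------

    @classmethod
    def from_points(cls, points, widths=None, width: float = 1.0) -> "Filament":
        """Build a filament from polyline vertices; the raster chain is
        filled in with Bresenham segments.  ``widths`` may be per-vertex
        (interpolated along the chain) or omitted (constant ``width``)."""
        pts = np.asarray(points, dtype=int)
        chain = [pts[0]]
        vidx = [0]
        for a, b in zip(pts[:-1], pts[1:]):
            seg = bresenham_line(a, b)
            chain.extend(seg[1:])
            vidx.append(len(chain) - 1)
        chain = np.asarray(chain, dtype=int)
        if widths is None:
            w = np.full(len(chain), float(width))
        else:
            wv = np.asarray(widths, dtype=float)
            w = np.interp(np.arange(len(chain)), vidx, wv)
        return cls(chain=chain, widths=w, vertex_idx=np.asarray(vidx))

    # -- geometry ---------------------------------------------------------

    @property
    def points(self) -> np.ndarray:
        """Polyline vertices (piece endpoints)."""
        return self.chain[self.vertex_idx]

    @property
    def length(self) -> float:
        return polyline_length(self.points)

    @property
    def mean_width(self) -> float:
        return float(np.mean(self.widths))

    def piece_orientations(self) -> np.ndarray:
        """Orientation (degrees, [0, 180)) of each straight piece."""
        pts = self.points.astype(float)
        out = []
        for a, b in zip(pts[:-1], pts[1:]):
            d = b - a
            if d[0] == 0 and d[1] == 0:
                out.append(out[-1] if out else 0.0)
            else:
                out.append(orientation_of(d[0], d[1]))
        return np.asarray(out)

    def pixel_orientations(self) -> np.ndarray:
        """Per-chain-pixel orientation = orientation of the piece the pixel
        belongs to (vertices belong to the preceding piece, the first
        vertex to the first piece)."""
        pieces = self.piece_orientations()
        out = np.empty(len(self.chain))
        for k in range(len(pieces)):
            lo = self.vertex_idx[k]
            hi = self.vertex_idx[k + 1]
            out[lo : hi + 1] = pieces[k]
        return out

    def pixel_set(self, shape, min_diameter: int = 1) -> np.ndarray:
        """Boolean mask of the pixels covered by the filament: the chain
        dilated by the per-pixel width (at least ``min_diameter``)."""
        d = np.maximum(self.widths, max(min_diameter, 1)).astype(int)
        return stamp_disks(shape, self.chain, d)

    def coverage_mask(self, shape) -> np.ndarray:
        """Pixel claim footprint: like :meth:`pixel_set` but never thinner
        than the filament's mean width, so a trace that hugged the edge of
        a stroke (where the width map is small) still covers the stroke."""
        return self.pixel_set(shape, min_diameter=int(round(self.mean_width)))

    def chain_pixel_set(self) -> set:
        return {(int(x), int(y)) for x, y in self.chain}

    def sub_filament(self, lo: int, hi: int) -> "Filament":
        """Filament restricted to chain indices [lo, hi] inclusive."""
        if hi - lo < 1:
            raise ValueError("sub-filament too short")
        keep = [lo] + [int(v) for v in self.vertex_idx if lo < v < hi] + [hi]
        vidx = np.asarray(keep) - lo
        return Filament(
            chain=self.chain[lo : hi + 1].copy(),
            widths=self.widths[lo : hi + 1].copy(),
            vertex_idx=vidx,
            score=float(np.sum(self.widths[lo : hi + 1])),
        )
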