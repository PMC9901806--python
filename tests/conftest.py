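"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest

import filatrack as flt
from filatrack import synthetic as syn


# ---------------------------------------------------------------------------
# independent oracles (pure-python, no reuse of package internals)


def width_map_oracle(mask: np.ndarray, tolerance: float = 0.0) -> np.ndarray:
    """Per-pixel disk growing by direct enumeration: the largest diameter d
    such that every diameter up to d keeps the miss fraction within
    tolerance (growth stops at the first failure)."""
    h, w = mask.shape
    out = np.zeros((h, w), dtype=int)
    for y in range(h):
        for x in range(w):
            if not mask[y, x]:
                continue
            d = 0
            while True:
                cand = d + 1
                r = cand / 2.0
                ri = int(math.floor(r))
                hits = misses = 0
                for dy in range(-ri, ri + 1):
                    for dx in range(-ri, ri + 1):
                        if dx * dx + dy * dy <= r * r + 1e-9:
                            xx, yy = x + dx, y + dy
                            if 0 <= xx < w and 0 <= yy < h and mask[yy, xx]:
                                hits += 1
                            else:
                                misses += 1
                total = hits + misses
                if misses <= tolerance * total + 1e-9:
                    d = cand
                else:
                    break
                if d > max(h, w) * 2:
                    break
            out[y, x] = d
    return out


def ray_mean_oracle(diameters: np.ndarray, start, angle_deg: float, length: int) -> float:
    """Independent rasterization of the directional mean width."""
    h, w = diameters.shape
    rad = math.radians(angle_deg)
    dx, dy = math.cos(rad), -math.sin(rad)
    vals = []
    for i in range(1, length + 1):
        x = round(start[0] + i * dx)
        y = round(start[1] + i * dy)
        vals.append(diameters[y, x] if 0 <= x < w and 0 <= y < h else 0.0)
    return float(np.mean(vals))


def random_mask(rng: np.random.Generator, shape=(16, 16), p: float = 0.5) -> np.ndarray:
    return rng.random(shape) < p


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def stripe_mask():
    """Horizontal stripe: rows 48..52 foreground (width-5 band)."""
    mask = np.zeros((100, 120), dtype=bool)
    mask[48:53, 10:110] = True
    return mask


@pytest.fixture
def three_stroke_image(tmp_path):
    """Noiseless 3-stroke fixture image written as TIFF, plus its truth."""
    import tifffile

    strokes = [
        syn.line_stroke((40, 60), (200, 90), width=5),
        syn.arc_stroke((128, 190), 60, -np.pi * 0.55, -np.pi * 0.1, width=5),
        syn.line_stroke((30, 220), (180, 140), width=5),
    ]
    img, truth = syn.render_strokes(strokes, shape=(256, 256))
    path = tmp_path / "three_strokes.tif"
    tifffile.imwrite(path, img)
    return path, img, truth
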