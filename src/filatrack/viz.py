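"""Overlay PNG writers for visual quality control."""

from __future__ import annotations

import numpy as np
import imageio.v3 as iio

__all__ = ["save_overlay", "save_persistence_overlay"]

_ORANGE = (255, 140, 0)

# simple fixed palette cycled by persistence / lifeline id
_PALETTE = [
    (228, 26, 28),
    (55, 126, 184),
    (77, 175, 74),
    (152, 78, 163),
    (255, 127, 0),
    (255, 255, 51),
    (166, 86, 40),
    (247, 129, 191),
]


def _to_rgb(img: np.ndarray) -> np.ndarray:
    g = np.asarray(img, dtype=float)
    if g.max() > 0:
        g = g / g.max() * 255.0
    g = g.astype(np.uint8)
    return np.stack([g, g, g], axis=-1)


def save_overlay(img, filaments, path, color=_ORANGE) -> None:
    """Raw image with filament chains painted on top."""
    rgb = _to_rgb(img)
    h, w = rgb.shape[:2]
    for f in filaments:
        for x, y in f.chain:
            if 0 <= x < w and 0 <= y < h:
                rgb[y, x] = color
    iio.imwrite(path, rgb)


def save_persistence_overlay(img, frame_index, lifelines, frames, path) -> None:
    """Filaments of one frame color-coded by lifeline persistence."""
    rgb = _to_rgb(img)
    h, w = rgb.shape[:2]
    for dyn in lifelines:
        if frame_index not in dyn.frames:
            continue
        f = frames[frame_index][dyn.frames[frame_index]]
        color = _PALETTE[min(dyn.persistence - 1, len(_PALETTE) - 1)]
        for x, y in f.chain:
            if 0 <= x < w and 0 <= y < h:
                rgb[y, x] = color
    iio.imwrite(path, rgb)
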