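"""Image loading, filter pipelines and binarization.

The filter pipeline mirrors a plugin registry: filters are registered by
name together with a parameter schema, and pipelines are serialized as a
JSON array of ``{"name": ..., "params": {...}}`` entries so that a filter
list can be saved and re-imported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import imageio.v3 as iio
import numpy as np
import tifffile
from scipy import ndimage
from skimage.filters import threshold_local, threshold_otsu

__all__ = [
    "FilterSpec",
    "FilterPipeline",
    "register_filter",
    "registered_filters",
    "apply_pipeline",
    "binarize",
    "load_image",
    "load_stack",
]


# ---------------------------------------------------------------------------
# filter registry


@dataclass(frozen=True)
class _ParamSpec:
    kind: type
    lo: float
    hi: float
    default: float


@dataclass(frozen=True)
class _FilterDef:
    fn: Callable
    params: dict


_REGISTRY: dict[str, _FilterDef] = {}


def register_filter(name: str, fn: Callable, params: dict | None = None) -> None:
    """Register a filter under ``name``.

    ``params`` maps a parameter name to ``(type, low, high, default)``.
    Registering a filter requires no change to pipeline code.
    """
    schema = {
        k: _ParamSpec(*v) for k, v in (params or {}).items()
    }
    _REGISTRY[name] = _FilterDef(fn=fn, params=schema)


def registered_filters() -> list[str]:
    return sorted(_REGISTRY)


register_filter(
    "gaussian",
    lambda img, sigma: ndimage.gaussian_filter(img.astype(float), sigma=sigma),
    {"sigma": (float, 0.0, 50.0, 1.0)},
)
register_filter(
    "laplace",
    lambda img: ndimage.laplace(img.astype(float)),
)
register_filter(
    "median",
    lambda img, size: ndimage.median_filter(img, size=int(size)),
    {"size": (int, 1, 99, 3)},
)
register_filter(
    "mean",
    lambda img, size: ndimage.uniform_filter(img.astype(float), size=int(size)),
    {"size": (int, 1, 99, 3)},
)
register_filter(
    "invert",
    lambda img: np.max(img) - img,
)


# ---------------------------------------------------------------------------
# pipeline


@dataclass(frozen=True)
class FilterSpec:
    name: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in _REGISTRY:
            raise ValueError(
                f"unknown filter {self.name!r}; registered: {registered_filters()}"
            )
        schema = _REGISTRY[self.name].params
        for k, v in self.params.items():
            if k not in schema:
                raise ValueError(f"filter {self.name!r} has no parameter {k!r}")
            ps = schema[k]
            if not (ps.lo <= v <= ps.hi):
                raise ValueError(
                    f"{self.name}.{k}={v} outside [{ps.lo}, {ps.hi}]"
                )

    def resolved_params(self) -> dict:
        schema = _REGISTRY[self.name].params
        out = {k: ps.default for k, ps in schema.items()}
        out.update(self.params)
        return out


@dataclass(frozen=True)
class FilterPipeline:
    filters: tuple = ()

    @classmethod
    def from_list(cls, items: list) -> "FilterPipeline":
        return cls(tuple(FilterSpec(f["name"], dict(f.get("params", {}))) for f in items))

    def to_list(self) -> list:
        return [{"name": f.name, "params": dict(f.params)} for f in self.filters]

    @classmethod
    def from_json(cls, text: str) -> "FilterPipeline":
        return cls.from_list(json.loads(text))

    def to_json(self) -> str:
        return json.dumps(self.to_list())

    def __add__(self, other: "FilterPipeline") -> "FilterPipeline":
        return FilterPipeline(self.filters + other.filters)

    def __len__(self) -> int:
        return len(self.filters)


def apply_pipeline(img: np.ndarray, pipe: FilterPipeline) -> np.ndarray:
    """Run the filter pipeline; the empty pipeline returns the input unchanged."""
    out = img
    for spec in pipe.filters:
        out = _REGISTRY[spec.name].fn(out, **spec.resolved_params())
        if out.shape != img.shape:
            raise RuntimeError(f"filter {spec.name!r} changed the image shape")
    return out


# ---------------------------------------------------------------------------
# binarization


def binarize(img: np.ndarray, method: str = "global_otsu", **params) -> np.ndarray:
    """Binarize a grayscale image; foreground (True) = filament candidates.

    Methods: ``global_otsu`` (default; a constant image yields an empty
    foreground), ``local_mean`` (``block_size``, ``offset``) and
    ``fixed_threshold`` (``threshold``; strictly-greater comparison).
    """
    img = np.asarray(img)
    if method == "global_otsu":
        if np.ptp(img) == 0:
            return np.zeros(img.shape, dtype=bool)
        return img > threshold_otsu(img)
    if method == "local_mean":
        block = int(params.get("block_size", 51))
        if block % 2 == 0:
            raise ValueError("block_size must be odd")
        offset = float(params.get("offset", 0.0))
        t = threshold_local(img.astype(float), block_size=block, method="mean", offset=offset)
        return img > t
    if method == "fixed_threshold":
        if "threshold" not in params:
            raise ValueError("fixed_threshold requires 'threshold'")
        return img > float(params["threshold"])
    raise ValueError(f"unknown binarization method {method!r}")


# ---------------------------------------------------------------------------
# loading

_LUMA = np.array([0.2126, 0.7152, 0.0722])


def _to_gray(plane: np.ndarray, channel: int | None) -> np.ndarray:
    if plane.ndim == 2:
        return plane
    if plane.ndim == 3 and plane.shape[-1] in (3, 4):
        if channel is not None:
            return plane[..., channel]
        # default: ITU-R 709 luminance of the first three channels
        return (plane[..., :3].astype(float) @ _LUMA)
    raise ValueError(f"cannot interpret image of shape {plane.shape} as 2D grayscale")


def load_image(path, frame_index: int | None = None, channel: int | None = None) -> np.ndarray:
    """Load one 2D grayscale plane from a PNG or (possibly multi-page) TIFF."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            n = len(tf.pages)
            idx = 0 if frame_index is None else int(frame_index)
            if not (0 <= idx < n):
                raise IndexError(f"frame_index {idx} out of range for {n}-page stack")
            plane = tf.pages[idx].asarray()
    else:
        plane = iio.imread(path)
        if plane.ndim == 3 and plane.shape[-1] not in (3, 4):
            # stacked non-TIFF: treat axis 0 as frames
            idx = 0 if frame_index is None else int(frame_index)
            if not (0 <= idx < plane.shape[0]):
                raise IndexError(f"frame_index {idx} out of range")
            plane = plane[idx]
        elif frame_index not in (None, 0):
            raise IndexError(f"frame_index {frame_index} out of range for single image")
    gray = _to_gray(plane, channel)
    if not np.all(np.isfinite(np.asarray(gray, dtype=float))):
        raise ValueError("image contains non-finite intensities")
    return gray


def load_stack(path, channel: int | None = None) -> np.ndarray:
    """Load all frames of an image file as a (T, H, W) array."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            frames = [_to_gray(p.asarray(), channel) for p in tf.pages]
    else:
        arr = iio.imread(path)
        if arr.ndim == 2:
            frames = [arr]
        elif arr.ndim == 3 and arr.shape[-1] in (3, 4):
            frames = [_to_gray(arr, channel)]
        else:
            frames = [_to_gray(a, channel) for a in arr]
    return np.stack(frames)
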