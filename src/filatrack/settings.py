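"""Serializable settings covering every processing stage.

The settings file is a versioned JSON document; loading is strict (an
unknown key is an error naming the key) and ``load(save(s)) == s`` holds
field for field.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .curve_tracer import TracerSettings
from .preprocessing import FilterPipeline
from .sensing import SensorSettings
from .tracking import TrackingSettings

SCHEMA_VERSION = 1

__all__ = [
    "CellEventSettings",
    "ExportSettings",
    "Settings",
    "save_settings",
    "load_settings",
]


@dataclass
class CellEventSettings:
    min_area: int = 50  # pixels^2
    intersect_tolerance: float = 0.2


@dataclass
class ExportSettings:
    overlays: bool = False
    tracking_layout: str = "frame"  # 'frame' | 'id' | 'both'
    min_persistence: int = 1
    max_persistence: int | None = None


@dataclass
class Settings:
    version: int = SCHEMA_VERSION
    mode: str = "curved"  # 'curved' | 'straight'
    pipeline: list = field(default_factory=list)  # serialized filter list
    binarization_method: str = "global_otsu"
    binarization_params: dict = field(default_factory=dict)
    sensor: SensorSettings = field(default_factory=SensorSettings)
    tracer: TracerSettings = field(default_factory=TracerSettings)
    tracking: TrackingSettings = field(default_factory=TrackingSettings)
    cell_events: CellEventSettings = field(default_factory=CellEventSettings)
    export: ExportSettings = field(default_factory=ExportSettings)

    def filter_pipeline(self) -> FilterPipeline:
        return FilterPipeline.from_list(self.pipeline)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "Settings":
        data = dict(data)
        version = data.get("version", None)
        if version != SCHEMA_VERSION:
            raise ValueError(f"unsupported settings schema version: {version!r}")
        sub = {
            "sensor": SensorSettings,
            "tracer": TracerSettings,
            "tracking": TrackingSettings,
            "cell_events": CellEventSettings,
            "export": ExportSettings,
        }
        kwargs = {}
        top_fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - top_fields
        if unknown:
            raise ValueError(f"unknown settings keys: {sorted(unknown)}")
        for key, value in data.items():
            if key in sub:
                klass = sub[key]
                names = {f.name for f in dataclasses.fields(klass)}
                bad = set(value) - names
                if bad:
                    raise ValueError(f"unknown keys in {key!r}: {sorted(bad)}")
                kwargs[key] = klass(**value)
            else:
                kwargs[key] = value
        s = cls(**kwargs)
        FilterPipeline.from_list(s.pipeline)  # validate filter names/params
        return s


def save_settings(s: Settings, path) -> None:
    Path(path).write_text(json.dumps(s.to_dict(), indent=2, sort_keys=True))


def load_settings(path) -> Settings:
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"malformed settings file {path}: {e}") from e
    return Settings.from_dict(data)
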