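"""Pipeline configuration: one place for every tunable constant.

Every screen-design constant (top-hat radius 10 um, 0.2 GCU threshold,
area filters > 80 / > 250 um^2, GFP-score threshold 5, confluency-score
threshold 0.65, nine control wells, 240 usable inner wells, 72 h at 2 h
scans) appears as a named, overridable key and round-trips losslessly
through a YAML file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, get_type_hints

import yaml

from .expression_pd import PanelSpec
from .imaging import SegmentationParams
from .screen_scoring import ScoringConfig
from .synthetic_screen import LibrarySpec, RenderParams

__all__ = ["GridSpec", "PipelineConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class GridSpec:
    t_end_h: float = 72.0
    step_h: float = 2.0

    def times(self):
        from .reporter_kinetics import default_grid

        return default_grid(self.t_end_h, self.step_h)


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    grid: GridSpec = field(default_factory=GridSpec)
    noise_sd: float = 0.05
    field_count: int = 1
    cell_line: str = "4T1"
    library: LibrarySpec = field(default_factory=LibrarySpec)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    render: RenderParams = field(default_factory=RenderParams)
    panel: PanelSpec = field(default_factory=PanelSpec)
    gain_gcu_per_count: float = 1e-3


_SECTIONS = {f.name: f for f in dataclasses.fields(PipelineConfig)}


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj):
        return {f.name: _to_plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def _retuple(value: Any) -> Any:
    if isinstance(value, list):
        return tuple(_retuple(v) for v in value)
    return value


def _build(cls, data: dict) -> Any:
    hints = get_type_hints(cls)
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        origin = getattr(hints.get(f.name), "__origin__", None)
        kwargs[f.name] = _retuple(v) if origin is tuple or isinstance(v, list) else v
    return cls(**kwargs)


def config_to_dict(config: PipelineConfig) -> dict:
    return _to_plain(config)


def config_from_dict(data: dict) -> PipelineConfig:
    data = dict(data or {})
    kwargs: dict[str, Any] = {}
    for name, f in _SECTIONS.items():
        if name not in data:
            continue
        v = data.pop(name)
        if dataclasses.is_dataclass(f.type) or name in (
                "grid", "library", "segmentation", "scoring", "render", "panel"):
            cls = {"grid": GridSpec, "library": LibrarySpec,
                   "segmentation": SegmentationParams, "scoring": ScoringConfig,
                   "render": RenderParams, "panel": PanelSpec}[name]
            kwargs[name] = _build(cls, v)
        else:
            kwargs[name] = v
    if data:
        raise ValueError(f"unknown config keys: {sorted(data)}")
    return PipelineConfig(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data or {})


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
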