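"""YAML/JSON session configuration.

Every key mirrors a dataclass field; omitted keys keep their defaults.
Example::

    geometry:
      cortical_radius_mm: 6.0
      grid_spacing_mm: 1.0
    transducer:
      acoustic_power_w: 60.0
      focal_offset_mm: 0.0
    controller:
      target_elevation_c: 6.0
    duration_s: 720
    seed: 7
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from . import acoustics, sources, thermal, thermometry
from .control import ControllerConfig
from .geometry import GeometryParams
from .session import SessionConfig

_SECTIONS = {
    "geometry": GeometryParams,
    "transducer": acoustics.TransducerSpec,
    "medium": acoustics.MediumSpec,
    "source": sources.SourceParams,
    "thermal": thermal.ThermalParams,
    "controller": ControllerConfig,
    "thermometry": thermometry.ThermoConfig,
}

_SCALARS = ("duration_s", "seed", "element_size_mm", "truth_feedback")


def _build(cls, payload: dict):
    if payload is None:
        payload = {}
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - fields
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    if cls is thermometry.ThermoConfig:
        payload = dict(payload)
        if "drift" in payload:
            payload["drift"] = thermometry.DriftModel(**payload["drift"])
        if "masked_classes" in payload:
            payload["masked_classes"] = tuple(payload["masked_classes"])
    if cls is GeometryParams and "domain_extent_mm" in payload:
        payload = dict(payload)
        payload["domain_extent_mm"] = tuple(payload["domain_extent_mm"])
    return cls(**payload)


def session_from_dict(cfg: dict) -> SessionConfig:
    kwargs = {}
    for key, cls in _SECTIONS.items():
        if key in cfg:
            kwargs[key] = _build(cls, cfg[key])
    for key in _SCALARS:
        if key in cfg:
            kwargs[key] = cfg[key]
    unknown = set(cfg) - set(_SECTIONS) - set(_SCALARS)
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    return SessionConfig(**kwargs)


def load_session_config(path: str | Path) -> SessionConfig:
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return session_from_dict(data or {})


def session_to_dict(cfg: SessionConfig) -> dict:
    out: dict = {}
    for key, _cls in _SECTIONS.items():
        section = dataclasses.asdict(getattr(cfg, key))
        if key == "geometry":
            section["domain_extent_mm"] = list(section["domain_extent_mm"])
        if key == "thermometry":
            section["masked_classes"] = list(section["masked_classes"])
        out[key] = section
    for key in _SCALARS:
        out[key] = getattr(cfg, key)
    return out


def save_session_config(cfg: SessionConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(session_to_dict(cfg), sort_keys=False))
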