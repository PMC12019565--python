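"""Run configuration: a YAML-serializable record of every knob that affects
an analysis, with a stable content hash for provenance."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import yaml

from .calibration import CantileverSpec
from .forward_model import ChannelNoise, FieldSpec, MembraneModel, RampSpec
from .lockin import ShearDrive

__all__ = ["AnalysisParams", "RunConfig", "load_config", "save_config", "config_hash"]


@dataclass
class AnalysisParams:
    """Pipeline and statistics parameters (SI units)."""

    baseline_fraction: float = 0.2
    contact_k_sigma: float = 3.0
    noise_floor_multiplier: float = 3.0
    plateau_width: float = 1.0e-9
    rupture_jump_threshold: float = 1.0e-9
    band_lo: float = 1.5e-9
    band_hi: float = 2.5e-9
    map_mode: str = "band"
    weights_scheme: str = "queen"
    permutations: int = 9999
    seed: int = 0

    def __post_init__(self) -> None:
        if self.band_lo >= self.band_hi:
            raise ValueError("indentation band must have band_lo < band_hi")
        for name in ("baseline_fraction", "contact_k_sigma", "noise_floor_multiplier",
                     "plateau_width", "rupture_jump_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class RunConfig:
    cantilever: CantileverSpec = field(default_factory=CantileverSpec)
    drive: ShearDrive = field(default_factory=ShearDrive)
    model: MembraneModel = field(default_factory=MembraneModel)
    ramp: RampSpec = field(default_factory=RampSpec)
    field_spec: FieldSpec = field(default_factory=FieldSpec)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    inputs: list[str] = field(default_factory=list)
    output_dir: str = "."


_SECTIONS = {
    "cantilever": CantileverSpec,
    "drive": ShearDrive,
    "model": MembraneModel,
    "ramp": RampSpec,
    "field_spec": FieldSpec,
    "analysis": AnalysisParams,
}


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        d = {}
        for f in dataclasses.fields(obj):
            if f.name.startswith("_"):
                continue
            d[f.name] = _to_plain(getattr(obj, f.name))
        return d
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if hasattr(obj, "tolist"):
        return obj.tolist()
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def config_to_dict(cfg: RunConfig) -> dict:
    return _to_plain(cfg)


def config_from_dict(data: dict) -> RunConfig:
    kwargs: dict[str, Any] = {}
    for name, cls in _SECTIONS.items():
        section = dict(data.get(name, {}))
        if not section:
            kwargs[name] = cls()
            continue
        if name == "model" and "noise" in section and isinstance(section["noise"], dict):
            section["noise"] = ChannelNoise(**section["noise"])
        if name == "field_spec" and "shape" in section:
            section["shape"] = tuple(section["shape"])
        if name == "field_spec" and section.get("phase_mask") is not None:
            import numpy as np

            section["phase_mask"] = np.asarray(section["phase_mask"], dtype=bool)
        kwargs[name] = cls(**section)
    kwargs["inputs"] = list(data.get("inputs", []))
    kwargs["output_dir"] = data.get("output_dir", ".")
    return RunConfig(**kwargs)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the full configuration for artifact provenance."""
    canonical = json.dumps(config_to_dict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
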