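"""Pipeline configuration: one object holding every stage's parameters.

Configs load from TOML or JSON with section names matching the parameter
groups; omitted sections fall back to package defaults.  Every invariant
of the nested parameter groups is enforced at load time so a bad
configuration fails before any computation starts.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .design import DesignParams
from .detect import DetectionParams
from .metrics import MetricsParams
from .preprocess import BlinkParams, FilterParams
from .simulate import KinematicsParams, LatencyModel, NoiseAndArtifactParams

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    out_dir: str = "toolgaze_run"
    in_dir: str | None = None          # read existing gaze tables instead
    n_subjects: int = 2
    master_seed: int = 0
    write_gaze: bool = True
    dv: str = "srt"                    # srt | error
    log_level: str = "INFO"
    design: DesignParams = field(default_factory=DesignParams)
    kinematics: KinematicsParams = field(default_factory=KinematicsParams)
    latency: LatencyModel = field(default_factory=LatencyModel)
    noise: NoiseAndArtifactParams = field(
        default_factory=NoiseAndArtifactParams)
    filter: FilterParams = field(default_factory=FilterParams)
    blink: BlinkParams = field(default_factory=BlinkParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    metrics: MetricsParams = field(default_factory=MetricsParams)

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        self.design.validate()
        # frozen dataclasses validate in __post_init__; re-touch the pair
        # constraint that spans groups
        if self.detection.theta_all > self.detection.theta_big:
            raise ValueError("theta_all must not exceed theta_big")

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "design": DesignParams.from_dict,
    "kinematics": KinematicsParams,
    "latency": LatencyModel,
    "noise": NoiseAndArtifactParams,
    "filter": FilterParams,
    "blink": BlinkParams,
    "detection": DetectionParams,
    "metrics": MetricsParams,
}


def _from_dict(raw: dict) -> PipelineConfig:
    kw: dict = {}
    for section, ctor in _SECTIONS.items():
        if section in raw:
            val = raw.pop(section)
            if section in ("latency",) and isinstance(val, dict):
                for key in ("mu_by_condition",):
                    if key in val and isinstance(val[key], dict):
                        val[key] = tuple(val[key].items())
                if "soa_effect" in val and isinstance(val["soa_effect"], dict):
                    val["soa_effect"] = tuple(
                        (int(k), v) for k, v in val["soa_effect"].items())
            if section == "noise" and isinstance(val, dict) and \
                    "blink_duration_ms" in val:
                val["blink_duration_ms"] = tuple(val["blink_duration_ms"])
            if isinstance(val, dict):
                kw[section] = (ctor(val) if section == "design"
                               else ctor(**val))
            else:
                kw[section] = val
    kw.update(raw)
    cfg = PipelineConfig(**kw)
    cfg.validate()
    return cfg


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a TOML/JSON config file; keyword overrides win."""
    raw: dict = {}
    if path is not None:
        path = Path(path)
        if path.suffix == ".toml":
            raw = tomllib.loads(path.read_text())
        else:
            raw = json.loads(path.read_text())
    raw.update(overrides)
    return _from_dict(raw)
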