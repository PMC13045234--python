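"""Pipeline configuration: nested per-stage sections with YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .preprocess import PreprocessConfig
from .recognizer import ModelConfig
from .telemetry import TelemetryConfig

__all__ = ["SynthConfig", "EvalConfig", "PipelineConfig"]


@dataclass(frozen=True)
class SynthConfig:
    n_subjects: int = 4
    reps_per_cell: int = 10


@dataclass(frozen=True)
class EvalConfig:
    loso: bool = True
    val_fraction: float = 0.2


@dataclass
class PipelineConfig:
    master_seed: int = 0
    out_dir: str = "runs/default"
    synthgen: SynthConfig = field(default_factory=SynthConfig)
    telemetry: TelemetryConfig = field(default_factory=TelemetryConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    recognizer: ModelConfig = field(default_factory=ModelConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        if isinstance(source, (str, Path)) and Path(source).exists():
            raw = yaml.safe_load(Path(source).read_text())
        else:
            raw = yaml.safe_load(source)
        raw = raw or {}
        kwargs = {}
        section_types = dict(
            synthgen=SynthConfig, telemetry=TelemetryConfig,
            preprocess=PreprocessConfig, recognizer=ModelConfig,
            evaluation=EvalConfig,
        )
        valid = {f.name for f in fields(cls)}
        for key, value in raw.items():
            if key not in valid:
                raise ValueError(f"unknown config section: {key!r}")
            if key in section_types:
                value = _coerce(section_types[key], value)
            kwargs[key] = value
        return cls(**kwargs)


def _coerce(typ, value: dict):
    if value is None:
        return typ()
    names = {f.name for f in fields(typ)}
    unknown = set(value) - names
    if unknown:
        raise ValueError(f"unknown keys for {typ.__name__}: {sorted(unknown)}")
    value = {
        k: (tuple(v) if isinstance(v, list) else v) for k, v in value.items()
    }
    return typ(**value)
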