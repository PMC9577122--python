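"""Pipeline configuration: one human-readable YAML file, lossless
round trip, every stage's knobs in one place."""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from wsirisk.patch_classifiers import TrainConfig
from wsirisk.slide_inference import GPConfig
from wsirisk.tiling import TilingConfig

__all__ = ["PipelineConfig", "load_config", "save_config", "config_hash"]


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    data_dir: str = "data"
    out_dir: str = "out"
    tiling: TilingConfig = field(default_factory=TilingConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    gp: GPConfig = field(default_factory=GPConfig)
    denominator_mode: str = "all"
    survival_horizon: float | None = None
    bootstrap_iterations: int = 10_000

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tiling"]["marker_hue_windows"] = [
            list(w) for w in self.tiling.marker_hue_windows
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        tiling = dict(d.pop("tiling", {}))
        if "marker_hue_windows" in tiling:
            tiling["marker_hue_windows"] = tuple(
                tuple(w) for w in tiling["marker_hue_windows"]
            )
        train = dict(d.pop("train", {}))
        gp = dict(d.pop("gp", {}))
        return cls(
            tiling=TilingConfig(**tiling),
            train=TrainConfig(**train),
            gp=GPConfig(**gp),
            **d,
        )


def save_config(config: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def load_config(path) -> PipelineConfig:
    return PipelineConfig.from_dict(yaml.safe_load(Path(path).read_text()))


def config_hash(config: PipelineConfig) -> str:
    payload = yaml.safe_dump(config.to_dict(), sort_keys=True).encode("utf-8")
    return hashlib.sha256(payload).hexdigest()[:16]
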