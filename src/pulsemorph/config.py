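"""Pipeline configuration: YAML-backed, defaults equal the published values."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .quality import QualityConfig
from .seq2seq import ModelConfig
from .training import TrainConfig

logger = logging.getLogger(__name__)


@dataclass
class SynthConfig:
    n_subjects: int = 20
    record_duration_s: float = 960.0
    noise_sd: float = 0.0
    seed: int = 0


@dataclass
class PipelineConfig:
    fs: float = 125.0
    seed: int = 0
    scenario: str = "Mixno+DI"
    n_folds: int = 5
    synth: SynthConfig = field(default_factory=SynthConfig)
    quality: QualityConfig = field(default_factory=QualityConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    paths: dict = field(default_factory=lambda: {"workdir": "pulsemorph_run"})

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Build a config from an optional YAML file plus CLI overrides.

    Every key absent from the file keeps its published default; every
    override is logged so a run's provenance is explicit.
    """
    raw = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    for k, v in (overrides or {}).items():
        if v is not None:
            raw[k] = v
            logger.info("config override: %s=%r", k, v)

    def build(cls, key):
        sub = raw.get(key, {})
        if key == "model":
            for tup in ("encoder_units", "decoder_units"):
                if tup in sub:
                    sub[tup] = tuple(sub[tup])
        return cls(**sub)

    cfg = PipelineConfig(
        fs=float(raw.get("fs", 125.0)),
        seed=int(raw.get("seed", 0)),
        scenario=str(raw.get("scenario", "Mixno+DI")),
        n_folds=int(raw.get("n_folds", 5)),
        synth=build(SynthConfig, "synth"),
        quality=build(QualityConfig, "quality"),
        model=build(ModelConfig, "model"),
        training=build(TrainConfig, "training"),
        paths=raw.get("paths", {"workdir": "pulsemorph_run"}),
    )
    if cfg.synth.n_subjects < 1:
        raise ValueError("synth.n_subjects must be positive")
    return cfg


def provenance_block(cfg: PipelineConfig) -> dict:
    import numpy, scipy  # noqa: PLC0415

    return {
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
    }
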