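"""Run configuration: YAML round-trip, defaults, and provenance hashing.

A ``RunConfig`` collects everything a run needs — model architecture,
schedule, training hyperparameters, data source, condition registries and
the sampling plan — and serializes losslessly to YAML.  Every experiment
writes its resolved config next to its outputs together with a content
hash, so any artifact can be regenerated from (config, seed, checkpoint).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .denoiser import DenoiserConfig

__all__ = ["RunConfig"]


def _default_model() -> dict:
    return {"resolution": 32, "base_channels": 16,
            "channel_multipliers": [1, 2, 4], "blocks_per_level": 1,
            "embedding_dim": 64, "attention_levels": [False, False, True]}


@dataclass
class RunConfig:
    model: dict = field(default_factory=_default_model)
    schedule: dict = field(default_factory=lambda: {"t_total": 1000,
                                                    "beta_start": None,
                                                    "beta_end": None})
    training: dict = field(default_factory=lambda: {"steps": 2000, "batch_size": 8,
                                                    "lr": 2e-3, "seed": 0,
                                                    "log_every": 100})
    data: dict = field(default_factory=lambda: {"kind": "synthetic",
                                                "n_per_domain": 64, "seed": 11})
    registries: dict = field(default_factory=lambda: {"labels": [], "genes": [],
                                                      "expression_genes": []})
    plan: dict = field(default_factory=lambda: {"n_first": 100, "n_second": 100})

    def denoiser_config(self) -> DenoiserConfig:
        m = self.model
        return DenoiserConfig(
            resolution=m["resolution"], base_channels=m["base_channels"],
            channel_multipliers=tuple(m["channel_multipliers"]),
            blocks_per_level=m["blocks_per_level"],
            embedding_dim=m["embedding_dim"],
            attention_levels=tuple(m["attention_levels"]))

    # ------------------------------------------------------------- round-trip
    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cfg = cls()
        for key, val in (raw or {}).items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config section {key!r}")
            section = getattr(cfg, key)
            section.update(val)
        return cfg

    def content_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(canon).hexdigest()[:16]
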