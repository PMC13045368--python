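"""Self-describing single-file checkpoints.

A checkpoint is a compressed ``.npz`` holding every parameter array plus a
JSON header with the denoiser config, the label/gene registries, the
schedule parameters, and arbitrary user metadata.  Loading rebuilds the
model and schedule exactly, so inference is fully reproducible from the
file alone.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .denoiser import Denoiser, DenoiserConfig, build_denoiser
from .schedule import NoiseSchedule, build_noise_schedule

__all__ = ["save_checkpoint", "load_checkpoint"]

_HEADER_KEY = "__header__"


def save_checkpoint(path, model: Denoiser, schedule: NoiseSchedule,
                    meta: dict | None = None) -> None:
    header = {
        "config": {
            "resolution": model.config.resolution,
            "base_channels": model.config.base_channels,
            "channel_multipliers": list(model.config.channel_multipliers),
            "blocks_per_level": model.config.blocks_per_level,
            "embedding_dim": model.config.embedding_dim,
            "attention_levels": list(model.config.attention_levels),
        },
        "labels": model.labels,
        "genes": model.genes,
        "expression_genes": model.expression_genes,
        "schedule": {
            "t_total": schedule.t_total,
            "beta_start": float(schedule.betas[0]),
            "beta_end": float(schedule.betas[-1]),
        },
        "meta": meta or {},
    }
    arrays = {f"param::{k}": p.data for k, p in model.params().items()}
    arrays[_HEADER_KEY] = np.frombuffer(
        json.dumps(header).encode("utf-8"), dtype=np.uint8)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path, **arrays)


def load_checkpoint(path) -> tuple[Denoiser, NoiseSchedule, dict]:
    """Rebuild (model, schedule, meta) from a checkpoint file."""
    with np.load(Path(path)) as npz:
        header = json.loads(bytes(npz[_HEADER_KEY]).decode("utf-8"))
        params = {k[len("param::"):]: npz[k] for k in npz.files
                  if k.startswith("param::")}
    cfg = header["config"]
    config = DenoiserConfig(
        resolution=cfg["resolution"], base_channels=cfg["base_channels"],
        channel_multipliers=tuple(cfg["channel_multipliers"]),
        blocks_per_level=cfg["blocks_per_level"],
        embedding_dim=cfg["embedding_dim"],
        attention_levels=tuple(cfg["attention_levels"]))
    model = build_denoiser(config, header["labels"], header["genes"], seed=0,
                           expression_genes=header.get("expression_genes"))
    model_params = model.params()
    missing = set(model_params) ^ set(params)
    if missing:
        raise ValueError(f"checkpoint parameter mismatch: {sorted(missing)[:5]}...")
    for k, p in model_params.items():
        if p.data.shape != params[k].shape:
            raise ValueError(f"shape mismatch for {k}")
        p.data = params[k].astype(p.data.dtype)
    sch = header["schedule"]
    schedule = build_noise_schedule(sch["t_total"], sch["beta_start"],
                                    sch["beta_end"])
    return model, schedule, header["meta"]
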