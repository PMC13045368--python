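"""Top-level reproducible runs: train, translate, edit, calibrate, evaluate.

Each run takes a ``RunConfig`` plus explicit inputs, writes its outputs
(images, TSV manifests, JSON reports) into an output directory, and records
the resolved config, its hash and the seed in every report, so reports are
reproducible artifacts rather than console output.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .checkpoint import load_checkpoint, save_checkpoint
from .conditioning import ConditionBundle
from .config import RunConfig
from .denoiser import build_denoiser
from .features import RandomProjectionExtractor, extract_features
from .io_utils import from_model_range, load_image, save_image, to_model_range
from .metrics import delta_fid, fit_feature_gaussian, fid, inverted_normalized_fid
from .schedule import build_noise_schedule
from .synthetic import generate_dataset, two_domain_spec
from .training import train_model
from .translate import calibrate_timesteps, make_timestep_plan, translate_batch

__all__ = ["train", "run_experiment"]


def _load_training_data(config: RunConfig):
    data = config.data
    if data.get("kind", "synthetic") == "synthetic":
        spec = two_domain_spec(resolution=config.model["resolution"])
        ds = generate_dataset(spec, n_per_domain=int(data.get("n_per_domain", 64)),
                              seed=int(data.get("seed", 11)))
        registries = {"labels": spec.labels, "genes": spec.gene_names,
                      "expression_genes": spec.expression_gene_names}
        return to_model_range(ds.images), ds.bundles, registries
    if data["kind"] == "manifest":
        manifest = pd.read_csv(data["manifest"], sep="\t")
        root = Path(data.get("image_dir", Path(data["manifest"]).parent))
        images, bundles = [], []
        genes = [c[4:] for c in manifest.columns if c.startswith("mut_")]
        expr = [c[5:] for c in manifest.columns if c.startswith("expr_")]
        for _, row in manifest.iterrows():
            images.append(to_model_range(load_image(root / row["image"])))
            genomic = {g: bool(row[f"mut_{g}"]) for g in genes} or None
            txn = {g: float(row[f"expr_{g}"]) for g in expr} or None
            bundles.append(ConditionBundle.make(str(row["domain"]), genomic, txn))
        registries = {"labels": sorted({b.categorical.label for b in bundles}),
                      "genes": genes, "expression_genes": expr}
        return np.stack(images), bundles, registries
    raise ValueError(f"unknown data kind {data.get('kind')!r}")


def train(config: RunConfig, out_dir) -> Path:
    """Train a checkpoint per the config; writes checkpoint, loss TSV, config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    images, bundles, registries = _load_training_data(config)
    labels = config.registries.get("labels") or registries["labels"]
    genes = config.registries.get("genes") or registries["genes"]
    expr = config.registries.get("expression_genes") or registries["expression_genes"]
    have = {b.categorical.label for b in bundles}
    if not have <= set(labels):
        raise ValueError(f"dataset labels {sorted(have)} not all registered "
                         f"in {labels}")
    tr = config.training
    model = build_denoiser(config.denoiser_config(), labels, genes,
                           seed=int(tr["seed"]), expression_genes=expr)
    schedule = build_noise_schedule(config.schedule["t_total"],
                                    config.schedule.get("beta_start"),
                                    config.schedule.get("beta_end"))
    log = train_model(model, schedule, images, bundles,
                      steps=int(tr["steps"]), batch_size=int(tr["batch_size"]),
                      lr=float(tr["lr"]), seed=int(tr["seed"]),
                      log_every=int(tr.get("log_every", 100)))
    ckpt = out / "checkpoint.npz"
    save_checkpoint(ckpt, model, schedule,
                    meta={"config_hash": config.content_hash(),
                          "trained_steps": int(tr["steps"])})
    log.to_tsv(out / "loss.tsv")
    config.to_yaml(out / "config.yaml")
    return ckpt


def _report(path: Path, kind: str, config: RunConfig, seed: int, body: dict) -> dict:
    report = {"kind": kind, "config_hash": config.content_hash(), "seed": seed}
    report.update(body)
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


def _read_image_dir(path) -> tuple[list[str], np.ndarray]:
    files = sorted(p for p in Path(path).iterdir()
                   if p.suffix.lower() in (".png", ".tif", ".tiff"))
    if not files:
        raise ValueError(f"no images found under {path}")
    return [f.name for f in files], np.stack([load_image(f) for f in files])


def run_experiment(kind: str, config: RunConfig, *, checkpoint=None,
                   in_dir=None, out_dir, src_bundle: ConditionBundle | None = None,
                   trg_bundle: ConditionBundle | None = None,
                   reference_dir=None, before_dir=None, seed: int = 0) -> dict:
    """Dispatch a non-training run; returns the JSON report as a dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    if kind in ("translate", "edit", "calibrate"):
        if checkpoint is None or not Path(checkpoint).exists():
            raise FileNotFoundError(f"checkpoint required for {kind!r} runs")
        model, schedule, _meta = load_checkpoint(checkpoint)
        plan = make_timestep_plan(schedule.t_total,
                                  int(config.plan["n_first"]),
                                  int(config.plan["n_second"]))

    if kind in ("translate", "edit"):
        if src_bundle is None or trg_bundle is None:
            raise ValueError("source and target bundles are required")
        names, images01 = _read_image_dir(in_dir)
        x = to_model_range(images01)
        y = translate_batch(x, model, [src_bundle] * len(names),
                            [trg_bundle] * len(names), schedule, plan)
        rows = []
        for name, img in zip(names, y):
            out_name = f"translated_{name}"
            save_image(out / out_name, from_model_range(img))
            rows.append({"input": name, "output": out_name})
        pd.DataFrame(rows).to_csv(out / "manifest.tsv", sep="\t", index=False)
        return _report(out / "report.json", kind, config, seed,
                       {"n_images": len(names),
                        "plan_steps": int(plan.steps.size)})

    if kind == "calibrate":
        names, images01 = _read_image_dir(in_dir)
        if src_bundle is None:
            raise ValueError("a source bundle is required for calibration")
        result = calibrate_timesteps(
            to_model_range(images01), model,
            [(src_bundle, trg_bundle or src_bundle)] * len(names), schedule,
            candidate_counts=config.plan.get("candidates", [50, 100, 200]),
            elbow_tolerance=float(config.plan.get("elbow_tolerance", 0.01)))
        return _report(out / "report.json", kind, config, seed,
                       {"n_star": result.n_star,
                        "plan_n_first": result.plan.n_first_half,
                        "plan_n_second": result.plan.n_second_half,
                        "candidate_ssim": {str(k): v for k, v
                                           in result.candidate_ssim.items()},
                        "allocation_ssim": {str(k): v for k, v
                                            in result.allocation_ssim.items()}})

    if kind == "evaluate":
        if in_dir is None or reference_dir is None:
            raise ValueError("evaluate needs --in (after) and reference dirs")
        extractor = RandomProjectionExtractor()
        _, after01 = _read_image_dir(in_dir)
        _, ref01 = _read_image_dir(reference_dir)
        f_after = extract_features(after01, extractor)
        f_ref = extract_features(ref01, extractor)
        body = {"fid": fid(fit_feature_gaussian(f_after),
                           fit_feature_gaussian(f_ref)),
                "extractor": extractor.name}
        if before_dir is not None:
            _, before01 = _read_image_dir(before_dir)
            f_before = extract_features(before01, extractor)
            body["delta_fid"] = delta_fid(f_before, f_after, f_ref)
        if f_ref.shape[0] >= 4:
            # real-vs-real split FID over synth-vs-real FID
            half = f_ref.shape[0] // 2
            body["inverted_normalized_fid"] = inverted_normalized_fid(
                f_ref[:half], f_ref[half:], f_after)
        return _report(out / "report.json", kind, config, seed, body)

    raise ValueError(f"unknown experiment kind {kind!r}")
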