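"""Conditional eps-prediction training.

The denoiser is trained with the plain DDPM objective: sample a timestep
uniformly and Gaussian noise per item, form the noisy image through the
forward marginal, and minimize the mean squared error between injected and
predicted noise.  No auxiliary classifier or guidance weight is involved;
the conditional network alone carries the domain/omics information, which
is exactly what the deterministic translation bridges sample from.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .conditioning import ConditionBundle
from .denoiser import Denoiser
from .nn import Adam, Tensor
from .schedule import NoiseSchedule

__all__ = ["training_loss", "train_model", "TrainLog"]


def _per_item_draws(item_seeds, shape, t_total):
    ts, epss = [], []
    for s in item_seeds:
        rng = np.random.default_rng(int(s))
        ts.append(int(rng.integers(0, t_total)))
        epss.append(rng.standard_normal(shape).astype(np.float32))
    return np.array(ts), np.stack(epss)


def training_loss(model: Denoiser, images: np.ndarray,
                  bundles: list[ConditionBundle], schedule: NoiseSchedule,
                  rng_seed: int, item_seeds: list[int] | None = None) -> Tensor:
    """MSE between injected and predicted noise, averaged over batch/pixels.

    `images` is BxHxWx3 in [-1, 1].  Each item's timestep and noise derive
    from its own seed (defaulting to a deterministic spawn of ``rng_seed``),
    so the loss is invariant to batch order when items keep their seeds.
    Returns the scalar loss as a graph tensor; call ``.backward()`` to get
    parameter gradients.
    """
    images = np.asarray(images, dtype=np.float32)
    if images.ndim == 3:
        images = images[None]
    if images.shape[0] == 0:
        raise ValueError("batch must be nonempty")
    if images.shape[0] != len(bundles):
        raise ValueError(f"{images.shape[0]} images but {len(bundles)} bundles")
    if item_seeds is None:
        item_seeds = [np.random.SeedSequence([int(rng_seed), i]).generate_state(1)[0]
                      for i in range(images.shape[0])]
    ts, eps = _per_item_draws(item_seeds, images.shape[1:], schedule.t_total)
    ab = schedule.alpha_bars[ts].astype(np.float32)[:, None, None, None]
    x_t = np.sqrt(ab) * images + np.sqrt(1.0 - ab) * eps
    eps_hat = model.forward_batch(x_t.transpose(0, 3, 1, 2), ts, bundles)
    diff = eps_hat - Tensor(eps.transpose(0, 3, 1, 2))
    return (diff * diff).mean()


@dataclass
class TrainLog:
    steps: list[int] = field(default_factory=list)
    losses: list[float] = field(default_factory=list)
    wall: list[float] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        lines = ["step\tloss\twall_seconds"]
        lines += [f"{s}\t{l:.6f}\t{w:.3f}"
                  for s, l, w in zip(self.steps, self.losses, self.wall)]
        Path(path).write_text("\n".join(lines) + "\n")


def train_model(model: Denoiser, schedule: NoiseSchedule, images: np.ndarray,
                bundles: list[ConditionBundle], *, steps: int,
                batch_size: int = 8, lr: float = 2e-3, seed: int = 0,
                log_every: int = 50, start_step: int = 0,
                callback=None) -> TrainLog:
    """Adam training loop; deterministic given (model, data, seed, steps).

    `images` are [-1, 1] floats, NxHxWx3.  Batches are drawn with
    replacement from a generator seeded per optimization step so resuming
    at ``start_step`` continues the same trajectory.
    """
    n = images.shape[0]
    if n == 0:
        raise ValueError("empty training set")
    opt = Adam(model.params(), lr=lr)
    log = TrainLog()
    t0 = time.monotonic()
    for step in range(start_step, start_step + steps):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), step]))
        idx = rng.integers(0, n, size=min(batch_size, n))
        batch = images[idx]
        batch_bundles = [bundles[i] for i in idx]
        item_seeds = [int(s) for s in rng.integers(0, 2 ** 31 - 1, size=idx.size)]
        model.zero_grad()
        loss = training_loss(model, batch, batch_bundles, schedule,
                             rng_seed=0, item_seeds=item_seeds)
        loss.backward()
        opt.step()
        if step % log_every == 0 or step == start_step + steps - 1:
            log.steps.append(step)
            log.losses.append(float(loss.data))
            log.wall.append(time.monotonic() - t0)
            if callback is not None:
                callback(step, float(loss.data))
    return log
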