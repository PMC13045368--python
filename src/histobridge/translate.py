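"""Deterministic diffusion bridges between condition domains.

Translation composes two DDIM solves of the probability-flow ODE with one
shared network: a forward solve under the *source* condition maps the image
to a Gaussian-like latent, and a backward solve under the *target* condition
maps the latent to the translated image.  Both solves iterate the update

    x_next = sqrt(abar_next) * x0_hat + sqrt(1 - abar_next) * eps_hat

where ``x0_hat`` and ``eps_hat`` come from a single network call at the
current step (they are algebraically linked through the forward marginal).
The solver may run on a reduced, strictly increasing subsequence of steps;
a calibration routine picks the smallest step budget whose outputs stay
SSIM-close to full sampling and then biases the budget toward the first
(low-noise) half, where extra steps help structure most.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .conditioning import ConditionBundle
from .denoiser import Denoiser
from .metrics import ssim_map
from .schedule import NoiseSchedule

__all__ = ["TimestepPlan", "make_timestep_plan", "encode_to_latent",
           "decode_from_latent", "translate_image", "translate_batch",
           "CalibrationResult", "calibrate_timesteps"]


@dataclass(frozen=True)
class TimestepPlan:
    """Strictly increasing subsequence of schedule indices to visit."""

    steps: np.ndarray
    t_total: int

    def __post_init__(self):
        steps = np.asarray(self.steps, dtype=np.int64)
        object.__setattr__(self, "steps", steps)
        if steps.size == 0:
            raise ValueError("timestep plan must be nonempty")
        if np.any(np.diff(steps) <= 0):
            raise ValueError("timestep plan must be strictly increasing")
        if steps[0] < 0 or steps[-1] >= self.t_total:
            raise ValueError(f"plan steps outside [0, {self.t_total})")

    @property
    def n_first_half(self) -> int:
        return int(np.sum(self.steps < self.t_total // 2))

    @property
    def n_second_half(self) -> int:
        return int(self.steps.size - self.n_first_half)


def make_timestep_plan(t_total: int, n_first: int, n_second: int) -> TimestepPlan:
    """Evenly spaced steps within each half of the schedule.

    The first half is ``[0, t_total//2)``, the second ``[t_total//2,
    t_total)``; each receives the requested number of evenly spaced
    (endpoint-inclusive) steps, deduplicated after rounding.
    """
    if n_first < 0 or n_second < 0 or n_first + n_second < 1:
        raise ValueError("need n_first, n_second >= 0 with a positive total")
    half = t_total // 2
    if n_first > half or n_second > t_total - half:
        raise ValueError(f"requested {n_first}+{n_second} steps exceed half sizes "
                         f"({half}, {t_total - half})")
    parts = []
    if n_first:
        parts.append(np.round(np.linspace(0, half - 1, n_first)))
    if n_second:
        parts.append(np.round(np.linspace(half, t_total - 1, n_second)))
    steps = np.unique(np.concatenate(parts).astype(np.int64))
    return TimestepPlan(steps=steps, t_total=t_total)


def _check(plan: TimestepPlan, schedule: NoiseSchedule) -> None:
    if plan.t_total != schedule.t_total:
        raise ValueError(f"plan built for T={plan.t_total} but schedule has "
                         f"T={schedule.t_total}")


def _as_batch(x: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 3:
        return x[None], True
    if x.ndim == 4:
        return x, False
    raise ValueError(f"expected HxWx3 or BxHxWx3 input, got shape {x.shape}")


def _ode_solve(x: np.ndarray, model: Denoiser, bundles: list[ConditionBundle],
               schedule: NoiseSchedule, plan: TimestepPlan,
               ascending: bool) -> np.ndarray:
    """Shared DDIM iteration.  `x` is BxHxWx3; bundles are per item.

    At each step the network is evaluated at the *current* noise level of
    ``x``; the predicted (x0_hat, eps_hat) pair is then recombined at the
    *next* level of the plan.  Ascending walks clean -> plan[-1] (the clean
    image sits at abar=1 with timestep label 0); descending walks
    plan[-1] -> clean.  Both directions call the network at the same
    (level, label) pairs, which is what makes the bridge approximately
    invertible.
    """
    abar = schedule.alpha_bars
    x_nchw = x.transpose(0, 3, 1, 2)
    steps = plan.steps
    if ascending:
        # (current level, target level) pairs; None stands for clean/abar=1
        moves = [(None if k == 0 else int(steps[k - 1]), int(steps[k]))
                 for k in range(steps.size)]
    else:
        moves = [(int(steps[k]),
                  None if k == 0 else int(steps[k - 1]))
                 for k in reversed(range(steps.size))]
    for cur, nxt in moves:
        ab_cur = 1.0 if cur is None else abar[cur]
        label = 0 if cur is None else cur
        eps_hat = model.forward_batch(x_nchw, np.full(x.shape[0], label),
                                      bundles).data
        x0_hat = (x_nchw - np.sqrt(1.0 - ab_cur) * eps_hat) / np.sqrt(ab_cur)
        ab_nxt = 1.0 if nxt is None else abar[nxt]
        x_nchw = np.sqrt(ab_nxt) * x0_hat + np.sqrt(1.0 - ab_nxt) * eps_hat
    return x_nchw.transpose(0, 2, 3, 1)


def encode_to_latent(x_src: np.ndarray, model: Denoiser,
                     src_bundle: ConditionBundle | list[ConditionBundle],
                     schedule: NoiseSchedule, plan: TimestepPlan) -> np.ndarray:
    """Forward ODE solve: clean image -> Gaussian-like latent at the last plan step."""
    _check(plan, schedule)
    xb, single = _as_batch(x_src)
    bundles = [src_bundle] * xb.shape[0] if isinstance(src_bundle, ConditionBundle) \
        else list(src_bundle)
    out = _ode_solve(xb, model, bundles, schedule, plan, ascending=True)
    return out[0] if single else out


def decode_from_latent(x_lat: np.ndarray, model: Denoiser,
                       trg_bundle: ConditionBundle | list[ConditionBundle],
                       schedule: NoiseSchedule, plan: TimestepPlan) -> np.ndarray:
    """Backward ODE solve: latent at the last plan step -> clean image."""
    _check(plan, schedule)
    xb, single = _as_batch(x_lat)
    bundles = [trg_bundle] * xb.shape[0] if isinstance(trg_bundle, ConditionBundle) \
        else list(trg_bundle)
    out = _ode_solve(xb, model, bundles, schedule, plan, ascending=False)
    return out[0] if single else out


def translate_image(x_src: np.ndarray, model: Denoiser,
                    src_bundle: ConditionBundle, trg_bundle: ConditionBundle,
                    schedule: NoiseSchedule, plan: TimestepPlan) -> np.ndarray:
    """Encode under the source condition, decode under the target condition."""
    lat = encode_to_latent(x_src, model, src_bundle, schedule, plan)
    return decode_from_latent(lat, model, trg_bundle, schedule, plan)


def translate_batch(x_src: np.ndarray, model: Denoiser,
                    src_bundles: list[ConditionBundle],
                    trg_bundles: list[ConditionBundle],
                    schedule: NoiseSchedule, plan: TimestepPlan) -> np.ndarray:
    """Vectorized translation of a BxHxWx3 stack with per-item bundles."""
    lat = encode_to_latent(x_src, model, src_bundles, schedule, plan)
    return decode_from_latent(lat, model, trg_bundles, schedule, plan)


# ------------------------------------------------------------------ calibration
@dataclass(frozen=True)
class CalibrationResult:
    plan: TimestepPlan
    n_star: int
    candidate_ssim: dict[int, float]
    allocation_ssim: dict[float, float]


def _mean_ssim(a: np.ndarray, b: np.ndarray) -> float:
    scores = [ssim_map(np.clip((x + 1) / 2, 0, 1), np.clip((y + 1) / 2, 0, 1))[0]
              for x, y in zip(a, b)]
    return float(np.mean(scores))


def _balanced(t_total: int, n: int) -> TimestepPlan:
    n1 = min((n + 1) // 2, t_total // 2)
    return make_timestep_plan(t_total, n1, n - n1)


def calibrate_timesteps(sample_images: np.ndarray, model: Denoiser,
                        bundles: list[ConditionBundle] | list[tuple[ConditionBundle, ConditionBundle]],
                        schedule: NoiseSchedule,
                        candidate_counts: list[int],
                        elbow_tolerance: float = 0.01,
                        first_half_fracs: tuple[float, ...] = (0.5, 0.6, 0.7, 0.8, 0.9),
                        ) -> CalibrationResult:
    """Pick a reduced step budget whose outputs stay close to full sampling.

    (1) translate the samples with the full plan; (2) for each candidate
    count, translate with a balanced reduced plan and record mean SSIM to the
    reference; (3) N* = the smallest candidate within ``elbow_tolerance`` of
    the best SSIM achieved; (4) re-allocate N* across the two schedule halves
    over ``first_half_fracs`` and keep the allocation with the best SSIM.
    """
    if not candidate_counts:
        raise ValueError("candidate_counts must be nonempty")
    counts = sorted(int(c) for c in candidate_counts)
    if counts[0] < 1 or counts[-1] > schedule.t_total:
        raise ValueError("candidate counts must lie in [1, t_total]")
    xb, _ = _as_batch(sample_images)
    pairs = [(b, b) if isinstance(b, ConditionBundle) else tuple(b) for b in bundles]
    src = [p[0] for p in pairs]
    trg = [p[1] for p in pairs]

    full = make_timestep_plan(schedule.t_total, schedule.t_total // 2,
                              schedule.t_total - schedule.t_total // 2)
    reference = translate_batch(xb, model, src, trg, schedule, full)

    candidate_ssim: dict[int, float] = {}
    for n in counts:
        plan = _balanced(schedule.t_total, n)
        out = translate_batch(xb, model, src, trg, schedule, plan)
        candidate_ssim[n] = _mean_ssim(out, reference)
    best = max(candidate_ssim.values())
    n_star = next(n for n in counts if candidate_ssim[n] >= best - elbow_tolerance)

    allocation_ssim: dict[float, float] = {}
    best_plan, best_score = None, -np.inf
    for frac in first_half_fracs:
        n1 = int(round(frac * n_star))
        n1 = min(max(n1, 0), schedule.t_total // 2)
        n2 = min(n_star - n1, schedule.t_total - schedule.t_total // 2)
        if n1 + n2 < 1:
            continue
        plan = make_timestep_plan(schedule.t_total, n1, n2)
        out = translate_batch(xb, model, src, trg, schedule, plan)
        score = _mean_ssim(out, reference)
        allocation_ssim[float(frac)] = score
        if score > best_score:
            best_plan, best_score = plan, score
    assert best_plan is not None
    return CalibrationResult(plan=best_plan, n_star=n_star,
                             candidate_ssim=candidate_ssim,
                             allocation_ssim=allocation_ssim)
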