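"""Variance schedule and the closed-form diffusion algebra.

The forward process gradually diffuses a clean image ``x0`` into noise:
``x_t = sqrt(abar_t) * x0 + sqrt(1 - abar_t) * eps`` with ``abar_t`` the
cumulative product of per-step retention factors ``alpha_t = 1 - beta_t``.
Deterministic DDIM sampling and its inversion only ever need ``abar_t`` and
the two conversions between ``eps`` and ``x0``, which live here.

Indexing convention: schedules are 0-based; ``alpha_bars[t]`` is the
cumulative product over steps ``0..t`` (the ``abar_{t+1}`` of 1-based
presentations).  The clean image sits "before" index 0 with abar = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NoiseSchedule", "build_noise_schedule", "q_sample", "predict_x0",
           "predict_eps"]

# DDPM convention at 1000 steps; rescaled with T so total noise is preserved
_BETA_START_1000 = 1e-4
_BETA_END_1000 = 2e-2


@dataclass(frozen=True)
class NoiseSchedule:
    """The beta ladder and its cumulative products.

    Attributes
    ----------
    t_total : int
        Number of diffusion steps T.
    betas, alphas, alpha_bars : ndarray, shape (t_total,)
        Per-step variances, retention factors ``1 - beta``, and cumulative
        products of the retention factors, all in (0, 1).
    """

    t_total: int
    betas: np.ndarray
    alphas: np.ndarray
    alpha_bars: np.ndarray

    def __post_init__(self):
        if self.t_total < 1:
            raise ValueError(f"t_total must be >= 1, got {self.t_total}")
        for name in ("betas", "alphas", "alpha_bars"):
            arr = getattr(self, name)
            if arr.shape != (self.t_total,):
                raise ValueError(f"{name} must have shape ({self.t_total},)")
        if np.any(self.betas <= 0) or np.any(self.betas >= 1):
            raise ValueError("betas must lie strictly in (0, 1)")
        if np.any(np.diff(self.alpha_bars) >= 0):
            raise ValueError("alpha_bars must be strictly decreasing")
        if self.alpha_bars[0] >= 1 or self.alpha_bars[-1] <= 0:
            raise ValueError("alpha_bars must lie strictly in (0, 1)")


def build_noise_schedule(t_total: int, beta_start: float | None = None,
                         beta_end: float | None = None,
                         kind: str = "linear") -> NoiseSchedule:
    """Build a linear beta schedule.

    When ``beta_start``/``beta_end`` are omitted they default to the
    1e-4..2e-2 ladder at T=1000, rescaled by ``1000/t_total`` so that the
    terminal signal level ``abar_T`` is roughly independent of T.
    """
    if kind != "linear":
        raise ValueError(f"unknown schedule kind {kind!r}")
    if t_total < 1:
        raise ValueError(f"t_total must be >= 1, got {t_total}")
    scale = 1000.0 / t_total
    if beta_start is None:
        beta_start = min(_BETA_START_1000 * scale, 0.5)
    if beta_end is None:
        beta_end = min(_BETA_END_1000 * scale, 0.999)
    if not (0.0 < beta_start <= beta_end < 1.0):
        raise ValueError(f"need 0 < beta_start <= beta_end < 1, "
                         f"got ({beta_start}, {beta_end})")
    betas = np.linspace(beta_start, beta_end, t_total, dtype=np.float64)
    alphas = 1.0 - betas
    alpha_bars = np.cumprod(alphas)
    return NoiseSchedule(t_total=t_total, betas=betas, alphas=alphas,
                         alpha_bars=alpha_bars)


def _check_t(t: int, schedule: NoiseSchedule) -> int:
    t = int(t)
    if not 0 <= t < schedule.t_total:
        raise IndexError(f"t={t} outside schedule range [0, {schedule.t_total})")
    return t


def q_sample(x0: np.ndarray, t: int, eps: np.ndarray,
             schedule: NoiseSchedule) -> np.ndarray:
    """Forward marginal: ``sqrt(abar_t) x0 + sqrt(1 - abar_t) eps``."""
    t = _check_t(t, schedule)
    x0 = np.asarray(x0)
    eps = np.asarray(eps)
    if eps.shape != x0.shape:
        raise ValueError(f"eps shape {eps.shape} != x0 shape {x0.shape}")
    ab = schedule.alpha_bars[t]
    return np.sqrt(ab) * x0 + np.sqrt(1.0 - ab) * eps


def predict_x0(x_t: np.ndarray, eps_hat: np.ndarray, t: int,
               schedule: NoiseSchedule) -> np.ndarray:
    """Invert the forward marginal: ``(x_t - sqrt(1 - abar_t) eps) / sqrt(abar_t)``."""
    t = _check_t(t, schedule)
    x_t = np.asarray(x_t)
    eps_hat = np.asarray(eps_hat)
    if eps_hat.shape != x_t.shape:
        raise ValueError(f"eps_hat shape {eps_hat.shape} != x_t shape {x_t.shape}")
    ab = schedule.alpha_bars[t]
    if ab <= 0:
        raise FloatingPointError(f"alpha_bar[{t}] = {ab} is not positive")
    return (x_t - np.sqrt(1.0 - ab) * eps_hat) / np.sqrt(ab)


def predict_eps(x_t: np.ndarray, x0_hat: np.ndarray, t: int,
                schedule: NoiseSchedule) -> np.ndarray:
    """The complementary conversion: noise implied by ``(x_t, x0_hat)``."""
    t = _check_t(t, schedule)
    ab = schedule.alpha_bars[t]
    return (np.asarray(x_t) - np.sqrt(ab) * np.asarray(x0_hat)) / np.sqrt(1.0 - ab)
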