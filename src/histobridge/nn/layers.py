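"""Neural-network building blocks (numpy autodiff backend).

A module is a plain object exposing ``params()`` -> ordered dict of
name -> Parameter; composite modules prefix child names.  Initialization is
driven by an explicit ``numpy.random.Generator`` so identical seeds give
bit-identical parameters.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Parameter, Tensor, conv2d, narrow

__all__ = ["Module", "Linear", "Conv2d", "GroupNorm", "MLP",
           "SelfAttention2d", "Adam", "sinusoidal_embedding"]

DTYPE = np.float32


class Module:
    def params(self) -> dict[str, Parameter]:
        out: dict[str, Parameter] = {}
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                out[name] = val
            elif isinstance(val, Module):
                for k, v in val.params().items():
                    out[f"{name}.{k}"] = v
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        for k, v in item.params().items():
                            out[f"{name}.{i}.{k}"] = v
        return out

    def zero_grad(self) -> None:
        for p in self.params().values():
            p.zero_grad()

    def n_params(self) -> int:
        return sum(p.data.size for p in self.params().values())


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        scale = 0.0 if zero_init else np.sqrt(1.0 / n_in)
        self.w = Parameter((rng.standard_normal((n_in, n_out)) * scale).astype(DTYPE))
        self.b = Parameter(np.zeros(n_out, dtype=DTYPE))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 zero_init: bool = False):
        fan_in = c_in * k * k
        scale = 0.0 if zero_init else np.sqrt(1.0 / fan_in)
        self.w = Parameter((rng.standard_normal((c_out, c_in, k, k)) * scale).astype(DTYPE))
        self.b = Parameter(np.zeros(c_out, dtype=DTYPE))
        self.pad = k // 2

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, self.pad)


class GroupNorm(Module):
    """Group normalization over NCHW activations, composed from primitives."""

    def __init__(self, channels: int, groups: int = 8, eps: float = 1e-5):
        groups = min(groups, channels)
        while channels % groups:
            groups -= 1
        self.groups = groups
        self.eps = eps
        self.gamma = Parameter(np.ones((1, channels, 1, 1), dtype=DTYPE))
        self.beta = Parameter(np.zeros((1, channels, 1, 1), dtype=DTYPE))

    def __call__(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        g = self.groups
        xg = x.reshape(b, g, (c // g) * h * w)
        mu = xg.mean(axis=2, keepdims=True)
        cen = xg - mu
        var = (cen * cen).mean(axis=2, keepdims=True)
        norm = cen * (var + self.eps) ** -0.5
        return norm.reshape(b, c, h, w) * self.gamma + self.beta


class MLP(Module):
    """Two-layer perceptron with SiLU, the shape used by all condition heads."""

    def __init__(self, n_in: int, n_hidden: int, n_out: int, rng: np.random.Generator):
        self.fc1 = Linear(n_in, n_hidden, rng)
        self.fc2 = Linear(n_hidden, n_out, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).silu())


class SelfAttention2d(Module):
    """Single-head dot-product attention over spatial positions of an NCHW map."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.norm = GroupNorm(channels)
        self.qkv = Conv2d(channels, 3 * channels, 1, rng)
        self.proj = Conv2d(channels, channels, 1, rng, zero_init=True)
        self.channels = channels

    def __call__(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        qkv = self.qkv(self.norm(x))
        q = narrow(qkv, 1, 0, c).reshape(b, c, h * w).transpose(0, 2, 1)
        k = narrow(qkv, 1, c, c).reshape(b, c, h * w)
        v = narrow(qkv, 1, 2 * c, c).reshape(b, c, h * w).transpose(0, 2, 1)
        attn = ((q @ k) * (c ** -0.5)).softmax_lastdim()
        out = (attn @ v).transpose(0, 2, 1).reshape(b, c, h, w)
        return x + self.proj(out)


def sinusoidal_embedding(t: np.ndarray, dim: int, max_period: float = 10000.0) -> np.ndarray:
    """Standard transformer-style timestep embedding (constant, no gradient)."""
    t = np.asarray(t, dtype=np.float64).reshape(-1)
    half = dim // 2
    freqs = np.exp(-np.log(max_period) * np.arange(half) / half)
    ang = t[:, None] * freqs[None, :]
    emb = np.concatenate([np.cos(ang), np.sin(ang)], axis=1)
    if dim % 2:
        emb = np.concatenate([emb, np.zeros((t.size, 1))], axis=1)
    return emb.astype(DTYPE)


class Adam:
    """Adam optimizer over a fixed ordered parameter dict."""

    def __init__(self, params: dict[str, Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype)
            m = self.m[k]
            v = self.v[k]
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()
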