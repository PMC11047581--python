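"""Neural-network building blocks over the autodiff tensor engine.

Initialisation follows the usual fan-in scaling (Kaiming-uniform for
convolutions and linear maps) and is fully determined by the numpy
Generator handed to each layer, so a model built twice from the same seed
has bit-identical parameters.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, concat, embedding_lookup

__all__ = [
    "Module", "Linear", "Conv1d", "GroupNorm", "Embedding",
    "SelfAttention1d", "zeros", "kaiming_uniform",
]


def kaiming_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    bound = np.sqrt(1.0 / max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


def zeros(shape) -> np.ndarray:
    return np.zeros(shape)


class Module:
    """Minimal parameter container with named, ordered parameters."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            params.extend(_collect(value))
        return params

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []
        for name, value in vars(self).items():
            out.extend(_collect_named(value, f"{prefix}{name}"))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on parameters: {sorted(missing)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


def _collect(value):
    if isinstance(value, Tensor) and value.requires_grad:
        yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect(v)


def _collect_named(value, name):
    if isinstance(value, Tensor) and value.requires_grad:
        yield name, value
    elif isinstance(value, Module):
        yield from value.named_parameters(prefix=name + ".")
    elif isinstance(value, (list, tuple)):
        for i, v in enumerate(value):
            yield from _collect_named(v, f"{name}.{i}")


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 zero_init: bool = False):
        if zero_init:
            w = zeros((in_features, out_features))
        else:
            w = kaiming_uniform(rng, (in_features, out_features), in_features)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(zeros(out_features), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0,
                 zero_init: bool = False):
        fan_in = in_channels * kernel
        if zero_init:
            w = zeros((out_channels, in_channels, kernel))
        else:
            w = kaiming_uniform(rng, (out_channels, in_channels, kernel), fan_in)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(zeros(out_channels), requires_grad=True)
        self.stride = stride
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv1d(self.weight, self.bias, stride=self.stride, padding=self.padding)


class GroupNorm(Module):
    """Group normalisation over (channel-group, time) with learned affine."""

    def __init__(self, n_groups: int, n_channels: int, eps: float = 1e-5):
        if n_channels % n_groups:
            raise ValueError(f"channels {n_channels} not divisible by groups {n_groups}")
        self.n_groups = n_groups
        self.eps = eps
        self.weight = Tensor(np.ones(n_channels), requires_grad=True)
        self.bias = Tensor(zeros(n_channels), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        B, C, L = x.shape
        g = self.n_groups
        xg = x.reshape(B, g, (C // g) * L)
        mu = xg.mean(axis=2, keepdims=True)
        xc = xg - mu
        var = (xc * xc).mean(axis=2, keepdims=True)
        xn = xc * (var + self.eps) ** -0.5
        xn = xn.reshape(B, C, L)
        return xn * self.weight.reshape(1, C, 1) + self.bias.reshape(1, C, 1)


class Embedding(Module):
    def __init__(self, n_embeddings: int, dim: int, rng: np.random.Generator):
        self.weight = Tensor(rng.normal(0.0, 0.02, size=(n_embeddings, dim)),
                             requires_grad=True)

    def __call__(self, indices: np.ndarray) -> Tensor:
        idx = np.asarray(indices)
        if idx.min() < 0 or idx.max() >= self.weight.shape[0]:
            raise IndexError(
                f"embedding index out of range [0, {self.weight.shape[0]})")
        return embedding_lookup(self.weight, idx)


class SelfAttention1d(Module):
    """Single-head self-attention over the time axis of (B, C, L) maps."""

    def __init__(self, channels: int, rng: np.random.Generator, n_norm_groups: int = 8):
        self.norm = GroupNorm(min(n_norm_groups, channels), channels)
        self.qkv = Conv1d(channels, 3 * channels, 1, rng)
        self.proj = Conv1d(channels, channels, 1, rng)
        self.channels = channels

    def __call__(self, x: Tensor) -> Tensor:
        B, C, L = x.shape
        h = self.norm(x)
        qkv = self.qkv(h)
        q, k, v = qkv[:, :C, :], qkv[:, C:2 * C, :], qkv[:, 2 * C:, :]
        scores = (q.swapaxes(1, 2) @ k) * (C ** -0.5)   # (B, L, L)
        att = scores.softmax(axis=-1)
        out = (att @ v.swapaxes(1, 2)).swapaxes(1, 2)    # (B, C, L)
        return x + self.proj(out)
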