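"""Layers and optimization on top of :mod:`mfel.autograd`.

Provides the handful of building blocks the dual-branch network needs:
convolutions, linear maps, channel/sequence normalization, and Adam.
Parameter initialization is driven by an explicit numpy Generator so whole
models are reproducible from one integer seed.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autograd import Tensor


class Module:
    """Base class with recursive named-parameter discovery."""

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(full)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{full}.{i}", item

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)[:5]}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())


def parameter(data: np.ndarray) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    """Stride-1 convolution on a single [C,H,W] map; kernel 1 or 3."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 zero_init: bool = False, bias: bool = True):
        if kernel not in (1, 3):
            raise ValueError("kernel must be 1 or 3")
        self.kernel = kernel
        self.padding = kernel // 2
        fan_in = in_ch * kernel * kernel
        if zero_init:
            w = np.zeros((out_ch, in_ch, kernel, kernel))
        else:
            w = he_init(rng, (out_ch, in_ch, kernel, kernel), fan_in)
        self.weight = parameter(w)
        self.bias = parameter(np.zeros(out_ch)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, padding=self.padding)


class Linear(Module):
    """Affine map applied to the last axis."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 zero_init: bool = False, bias: bool = True):
        if zero_init:
            w = np.zeros((in_dim, out_dim))
        else:
            w = he_init(rng, (in_dim, out_dim), in_dim)
        self.weight = parameter(w)
        self.bias = parameter(np.zeros(out_dim)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class ChannelNorm(Module):
    """Normalize each channel of a [C,H,W] map over its spatial extent.

    Batch statistics are unavailable (the engine trains sample-by-sample),
    so instance-style normalization with learnable per-channel affine
    parameters is used; it behaves identically in training and inference.
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gain = parameter(np.ones((channels, 1, 1)))
        self.shift = parameter(np.zeros((channels, 1, 1)))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(1, 2), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(1, 2), keepdims=True)
        return xc * ((var + self.eps) ** -0.5) * self.gain + self.shift


class LayerNorm(Module):
    """Normalize the last axis of a [..., C] tensor."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gain = parameter(np.ones(dim))
        self.shift = parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * ((var + self.eps) ** -0.5) * self.gain + self.shift


class Adam:
    """Adam with the ecosystem-default moment coefficients.

    State is keyed by parameter name so it can round-trip through a
    checkpoint exactly (trajectory-preserving resume).
    """

    def __init__(self, named_params: list[tuple[str, Tensor]], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(named_params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = {name: np.zeros_like(p.data) for name, p in self.params}
        self.v = {name: np.zeros_like(p.data) for name, p in self.params}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for name, p in self.params:
            g = p.grad
            if g is None:
                continue
            m = self.m[name]
            v = self.v[name]
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def state_dict(self) -> dict:
        state: dict = {"t": self.t}
        for name in self.m:
            state[f"m::{name}"] = self.m[name].copy()
            state[f"v::{name}"] = self.v[name].copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        for name in self.m:
            self.m[name] = np.asarray(state[f"m::{name}"], dtype=self.m[name].dtype).copy()
            self.v[name] = np.asarray(state[f"v::{name}"], dtype=self.v[name].dtype).copy()
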