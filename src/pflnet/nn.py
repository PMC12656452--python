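"""Layers, initialisation and SGD optimisation on top of :mod:`pflnet.autodiff`."""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .autodiff import Tensor, as_tensor, conv2d

__all__ = [
    "Module", "Conv2d", "Linear", "Sequential",
    "softmax", "log_softmax", "cross_entropy",
    "SGD", "cosine_lr",
]


class Module:
    """Base class: recursively collects parameters from attributes and lists."""

    def parameters(self) -> Iterator[Tensor]:
        for value in self.__dict__.values():
            yield from _params_of(value)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, value in self.__dict__.items():
            yield from _named_params_of(value, f"{prefix}{name}")

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: "
                                 f"{arr.shape} vs {p.data.shape}")
            p.data = arr


def _params_of(value):
    if isinstance(value, Tensor):
        if value.requires_grad:
            yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _params_of(v)


def _named_params_of(value, prefix):
    if isinstance(value, Tensor):
        if value.requires_grad:
            yield prefix, value
    elif isinstance(value, Module):
        yield from value.named_parameters(prefix + ".")
    elif isinstance(value, (list, tuple)):
        for i, v in enumerate(value):
            yield from _named_params_of(v, f"{prefix}.{i}")


def _he_normal(rng: np.random.Generator, shape, fan_in, dtype) -> Tensor:
    std = math.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, std, size=shape).astype(dtype), requires_grad=True)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 padding: int = 0, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.weight = _he_normal(rng, (cout, cin, k, k), cin * k * k, dtype)
        self.bias = Tensor(np.zeros(cout, dtype=dtype), requires_grad=True)
        self.stride = stride
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias,
                      stride=self.stride, padding=self.padding)


class Linear(Module):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.weight = _he_normal(rng, (nout, nin), nin, dtype)
        self.bias = Tensor(np.zeros(nout, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        # x: (..., nin) -> (..., nout)
        return x @ self.weight.T + self.bias


class GroupNorm(Module):
    """Group normalisation over ``(B, C, H, W)`` activations.

    Statistics are computed per sample over channel groups, so inference is
    deterministic and independent of batch composition (no running stats).
    """

    def __init__(self, channels: int, groups: int = 8, eps: float = 1e-5,
                 dtype=np.float32):
        if channels % groups:
            groups = 1
        self.groups = groups
        self.eps = eps
        self.gamma = Tensor(np.ones((1, channels, 1, 1), dtype=dtype),
                            requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1), dtype=dtype),
                           requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        g = self.groups
        xg = x.reshape(b, g, (c // g) * h * w)
        mu = xg.mean(axis=2, keepdims=True)
        centred = xg - mu
        var = (centred * centred).mean(axis=2, keepdims=True)
        xhat = (centred / (var + self.eps).sqrt()).reshape(b, c, h, w)
        return xhat * self.gamma + self.beta


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def __call__(self, x):
        for layer in self.layers:
            x = layer(x) if isinstance(layer, (Module,)) else layer(x)
        return x


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    shift = x.max(axis=axis, keepdims=True).detach()
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    shift = x.max(axis=axis, keepdims=True).detach()
    z = x - shift
    return z - z.exp().sum(axis=axis, keepdims=True).log()


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood; logits (B, c), integer labels (B,)."""
    logits = as_tensor(logits)
    labels = np.asarray(labels, dtype=np.intp)
    b, c = logits.shape
    onehot = np.zeros((b, c), dtype=logits.dtype)
    onehot[np.arange(b), labels] = 1.0
    return -(log_softmax(logits, axis=1) * onehot).sum() / float(b)


class SGD:
    """SGD with momentum and decoupled parameter groups.

    ``groups`` is a list of dicts ``{"params": [...], "lr": base_lr,
    "schedule": callable(step)->scale or None}``; a ``None`` schedule keeps
    the learning rate constant.
    """

    def __init__(self, groups, momentum: float = 0.9, weight_decay: float = 0.0,
                 max_grad_norm: float | None = None):
        self.groups = []
        for g in groups:
            params = list(g["params"])
            self.groups.append({
                "params": params,
                "lr": float(g["lr"]),
                "schedule": g.get("schedule"),
                "velocity": [np.zeros_like(p.data) for p in params],
            })
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.max_grad_norm = max_grad_norm
        self.step_count = 0

    def _clip_gradients(self) -> None:
        """Rescale all gradients so their global L2 norm is bounded."""
        if self.max_grad_norm is None:
            return
        sq = 0.0
        for g in self.groups:
            for p in g["params"]:
                if p.grad is not None:
                    sq += float(np.sum(p.grad.astype(np.float64) ** 2))
        norm = np.sqrt(sq)
        if norm > self.max_grad_norm:
            scale = self.max_grad_norm / (norm + 1e-12)
            for g in self.groups:
                for p in g["params"]:
                    if p.grad is not None:
                        p.grad *= scale

    def zero_grad(self) -> None:
        for g in self.groups:
            for p in g["params"]:
                p.grad = None

    def current_lrs(self) -> list[float]:
        out = []
        for g in self.groups:
            scale = g["schedule"](self.step_count) if g["schedule"] else 1.0
            out.append(g["lr"] * scale)
        return out

    def step(self) -> None:
        self._clip_gradients()
        for g, lr in zip(self.groups, self.current_lrs()):
            for p, v in zip(g["params"], g["velocity"]):
                if p.grad is None:
                    continue
                grad = p.grad + self.weight_decay * p.data
                v *= self.momentum
                v += grad
                p.data = p.data - lr * v
        self.step_count += 1


def cosine_lr(total_steps: int):
    """Cosine annealing from 1 down to ~0 over ``total_steps`` optimiser steps."""
    total = max(int(total_steps), 1)

    def schedule(step: int) -> float:
        t = min(step, total)
        return 0.5 * (1.0 + math.cos(math.pi * t / total))

    return schedule
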