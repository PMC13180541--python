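"""Module system, standard layers and the AdamW optimizer.

Layer parameters are initialized from a process-wide seeded generator
(:func:`manual_seed`) so that constructing the same architecture under the
same seed yields bit-identical parameters.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .tensor import (
    Parameter,
    Tensor,
    as_tensor,
    conv2d,
    gelu,
    layernorm,
    matmul,
    relu,
    sigmoid,
    softmax,
)

__all__ = [
    "DEFAULT_DTYPE",
    "manual_seed",
    "Module",
    "ModuleList",
    "Sequential",
    "Identity",
    "Conv2d",
    "Linear",
    "LayerNorm",
    "LayerNorm2d",
    "BatchNorm2d",
    "softmax",
    "silu",
    "AdamW",
    "clip_grad_norm",
]

_RNG = np.random.default_rng(0)

#: dtype for freshly initialized parameters; float32 keeps training fast on
#: CPU BLAS while tests may install float64 weights for tight tolerances.
DEFAULT_DTYPE = np.float32


def manual_seed(seed: int) -> None:
    """Reset the parameter-initialization stream."""
    global _RNG
    _RNG = np.random.default_rng(seed)


def _uniform(shape, bound: float, dtype=None) -> np.ndarray:
    return _RNG.uniform(-bound, bound, size=shape).astype(dtype or DEFAULT_DTYPE)


class Module:
    """Base class: parameter discovery, mode flags, state dicts."""

    def __init__(self) -> None:
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        out = self.forward(*args, **kwargs)
        if getattr(self, "_cam_capture", False):
            self._cam_activation = out
        return out

    def _children(self) -> Iterator[tuple[str, "Module"]]:
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_modules(self, prefix: str = "") -> Iterator[tuple[str, "Module"]]:
        yield prefix.rstrip("."), self
        for name, child in self._children():
            yield from child.named_modules(prefix + name + ".")

    def train(self) -> "Module":
        for _, m in self.named_modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for _, m in self.named_modules():
            m.training = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: v.data.copy() for k, v in self.named_parameters()}
        for name, m in self.named_modules():
            if isinstance(m, BatchNorm2d):
                state[f"{name}.running_mean" if name else "running_mean"] = (
                    m.running_mean.copy()
                )
                state[f"{name}.running_var" if name else "running_var"] = (
                    m.running_var.copy()
                )
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for key, value in state.items():
            if key in params:
                params[key].data = np.asarray(value).reshape(params[key].shape)
                continue
            if key.endswith("running_mean") or key.endswith("running_var"):
                mod_name, _, attr = key.rpartition(".")
                for name, m in self.named_modules():
                    if name == mod_name and isinstance(m, BatchNorm2d):
                        setattr(m, attr, np.asarray(value))
                        break


class ModuleList(Module):
    def __init__(self, modules=()) -> None:
        super().__init__()
        self.items = list(modules)

    def __iter__(self):
        return iter(self.items)

    def __len__(self):
        return len(self.items)

    def __getitem__(self, i):
        return self.items[i]

    def append(self, m: Module) -> None:
        self.items.append(m)


class Sequential(Module):
    def __init__(self, *modules: Module) -> None:
        super().__init__()
        self.items = list(modules)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, i):
        return self.items[i]

    def forward(self, x):
        for m in self.items:
            x = m(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        groups: int = 1,
        bias: bool = True,
    ) -> None:
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.groups = groups
        fan_in = (in_channels // groups) * kernel_size * kernel_size
        bound = 1.0 / math.sqrt(fan_in)
        self.weight = Parameter(
            _uniform(
                (out_channels, in_channels // groups, kernel_size, kernel_size), bound
            )
        )
        self.bias = Parameter(_uniform((out_channels,), bound)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(
            x,
            self.weight,
            self.bias,
            stride=self.stride,
            padding=self.padding,
            groups=self.groups,
        )


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True) -> None:
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        bound = 1.0 / math.sqrt(in_features)
        self.weight = Parameter(_uniform((in_features, out_features), bound))
        self.bias = Parameter(_uniform((out_features,), bound)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = matmul(x, self.weight)
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    """Normalize over the last axis (token tensors ``(..., C)``)."""

    def __init__(self, num_features: int, eps: float = 1e-5) -> None:
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones(num_features, dtype=DEFAULT_DTYPE))
        self.bias = Parameter(np.zeros(num_features, dtype=DEFAULT_DTYPE))

    def forward(self, x: Tensor) -> Tensor:
        return layernorm(x, self.weight, self.bias, axis=-1, eps=self.eps)


class LayerNorm2d(Module):
    """Layer normalization over the channel axis of NCHW maps, per position."""

    def __init__(self, num_channels: int, eps: float = 1e-5) -> None:
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones((1, num_channels, 1, 1), dtype=DEFAULT_DTYPE))
        self.bias = Parameter(np.zeros((1, num_channels, 1, 1), dtype=DEFAULT_DTYPE))

    def forward(self, x: Tensor) -> Tensor:
        return layernorm(x, self.weight, self.bias, axis=1, eps=self.eps)


class BatchNorm2d(Module):
    def __init__(
        self, num_features: int, eps: float = 1e-5, momentum: float = 0.1
    ) -> None:
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones((1, num_features, 1, 1), dtype=DEFAULT_DTYPE))
        self.bias = Parameter(np.zeros((1, num_features, 1, 1), dtype=DEFAULT_DTYPE))
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            n = x.shape[0] * x.shape[2] * x.shape[3]
            unbiased = var.data.reshape(-1) * (n / max(n - 1, 1))
            self.running_mean = (
                1 - self.momentum
            ) * self.running_mean + self.momentum * mu.data.reshape(-1)
            self.running_var = (
                1 - self.momentum
            ) * self.running_var + self.momentum * unbiased
            return xc / (var + self.eps).sqrt() * self.weight + self.bias
        mu = self.running_mean.reshape(1, -1, 1, 1)
        var = self.running_var.reshape(1, -1, 1, 1)
        return (x - mu) / np.sqrt(var + self.eps) * self.weight + self.bias


def silu(x: Tensor) -> Tensor:
    return x * sigmoid(x)


class AdamW:
    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 1e-4,
    ) -> None:
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data = p.data - self.lr * (
                mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data
            )

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def clip_grad_norm(params: list[Parameter], max_norm: float) -> float:
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad**2).sum())
    norm = math.sqrt(total)
    if norm > max_norm > 0:
        scale = max_norm / (norm + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale
    return norm
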