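"""Parameterised layers and the module container system."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Parameter(Tensor):
    """A tensor that is updated by the optimiser."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Container with recursive parameter traversal and flat state dicts."""

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for k, item in enumerate(value):
                    if isinstance(item, Parameter):
                        yield f"{full}.{k}", item
                    elif isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{k}.")

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state dict mismatch: missing={sorted(missing)}, extra={sorted(extra)}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(
                    f"parameter {name}: shape {state[name].shape} != {p.data.shape}"
                )
            p.data = np.asarray(state[name], dtype=np.float64).copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


# ---------------------------------------------------------------------------
# basic layers
# ---------------------------------------------------------------------------

def _kaiming(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / max(fan_in, 1)), size=shape)


class Linear(Module):
    def __init__(
        self,
        n_in: int,
        n_out: int,
        rng: np.random.Generator,
        bias: bool = True,
        zero_init: bool = False,
    ):
        w = np.zeros((n_in, n_out)) if zero_init else _kaiming(rng, n_in, (n_in, n_out))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(n_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = ag.matmul(x, self.weight)
        if self.bias is not None:
            y = ag.add(y, self.bias)
        return y


class Conv2d(Module):
    """Stride-1 same-padding convolution."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: tuple[int, int],
        rng: np.random.Generator,
        bias: bool = True,
        zero_init: bool = False,
    ):
        kh, kw = kernel
        fan_in = in_channels * kh * kw
        w = (
            np.zeros((out_channels, in_channels, kh, kw))
            if zero_init
            else _kaiming(rng, fan_in, (out_channels, in_channels, kh, kw))
        )
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias)


class ConvTranspose2d(Module):
    """Stride-1 transposed convolution (adjoint of same-padding conv)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: tuple[int, int],
        rng: np.random.Generator,
        bias: bool = True,
    ):
        kh, kw = kernel
        fan_in = in_channels * kh * kw
        self.weight = Parameter(_kaiming(rng, fan_in, (in_channels, out_channels, kh, kw)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv_transpose2d(x, self.weight, self.bias)


class DepthwiseConv2d(Module):
    def __init__(
        self,
        channels: int,
        kernel: tuple[int, int],
        rng: np.random.Generator,
        bias: bool = True,
    ):
        kh, kw = kernel
        self.weight = Parameter(_kaiming(rng, kh * kw, (channels, kh, kw)))
        self.bias = Parameter(np.zeros(channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.depthwise_conv2d(x, self.weight, self.bias)


class DepthwiseSeparableConv2d(Module):
    """Depthwise spatial mixing followed by a 1x1 pointwise projection."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: tuple[int, int],
        rng: np.random.Generator,
    ):
        self.depthwise = DepthwiseConv2d(in_channels, kernel, rng)
        self.pointwise = Conv2d(in_channels, out_channels, (1, 1), rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.pointwise(self.depthwise(x))


# ---------------------------------------------------------------------------
# normalisation layers
# ---------------------------------------------------------------------------

class LayerNorm(Module):
    """Normalise over the trailing feature axis of (..., C)."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return ag.normalize(x, self.gamma, self.beta, axes=(-1,), eps=self.eps)


class InstanceNorm2d(Module):
    """Per-sample, per-channel spatial normalisation of (B, C, H, W)."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones((channels, 1, 1)))
        self.beta = Parameter(np.zeros((channels, 1, 1)))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return ag.normalize(x, self.gamma, self.beta, axes=(-2, -1), eps=self.eps)


class SequenceNorm(Module):
    """Per-channel normalisation over (B, T) of a (B, T, C) sequence.

    Plays the role of batch normalisation in the refiner's conv block;
    with per-sample training the sequence axis supplies the statistics.
    Batch statistics are always used (no running averages).
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return ag.normalize(x, self.gamma, self.beta, axes=(0, 1), eps=self.eps)


__all__ = [
    "Parameter",
    "Module",
    "Linear",
    "Conv2d",
    "ConvTranspose2d",
    "DepthwiseConv2d",
    "DepthwiseSeparableConv2d",
    "LayerNorm",
    "InstanceNorm2d",
    "SequenceNorm",
]
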