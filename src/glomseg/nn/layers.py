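"""Layer containers over the autodiff primitives.

Modules hold named :class:`Parameter` tensors and compose via attribute
nesting, mirroring the conventions of the mainstream frameworks so the
network code reads familiarly.  Initialization is He-style and always flows
from an explicit :class:`numpy.random.Generator` — there is no hidden global
RNG anywhere in the package.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .tensor import (Tensor, conv2d, instance_norm, linear, relu)

DTYPE = np.float32


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True)


class Module:
    """Base class: recursive parameter discovery and state (de)serialization."""

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=full + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{full}.{i}.")

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch; missing={sorted(missing)} "
                           f"unexpected={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=DTYPE)
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {name}: shape {arr.shape} != "
                                 f"{p.data.shape}")
            p.data = arr.copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / max(fan_in, 1))
    return rng.normal(0.0, std, size=shape).astype(DTYPE)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1,
                 padding: int = 0):
        self.stride = stride
        self.padding = padding
        fan_in = in_ch * kernel_size * kernel_size
        self.weight = Parameter(_he_init(rng, (out_ch, in_ch, kernel_size,
                                               kernel_size), fan_in))
        self.bias = Parameter(np.zeros(out_ch, dtype=DTYPE))

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding)


class InstanceNorm2d(Module):
    def __init__(self, channels: int):
        self.gamma = Parameter(np.ones(channels, dtype=DTYPE))
        self.beta = Parameter(np.zeros(channels, dtype=DTYPE))

    def __call__(self, x: Tensor) -> Tensor:
        return instance_norm(x, self.gamma, self.beta)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator):
        self.weight = Parameter(_he_init(rng, (out_features, in_features),
                                         in_features))
        self.bias = Parameter(np.zeros(out_features, dtype=DTYPE))

    def __call__(self, x: Tensor) -> Tensor:
        return linear(x, self.weight, self.bias)


class ResidualBlock(Module):
    """Pre-activation residual block: norm-relu-conv twice plus shortcut.

    A 1x1 projection is inserted on the shortcut when the channel count
    changes; otherwise the identity is used.
    """

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.norm1 = InstanceNorm2d(in_ch)
        self.conv1 = Conv2d(in_ch, out_ch, 3, rng, padding=1)
        self.norm2 = InstanceNorm2d(out_ch)
        self.conv2 = Conv2d(out_ch, out_ch, 3, rng, padding=1)
        self.proj = Conv2d(in_ch, out_ch, 1, rng) if in_ch != out_ch else None

    def __call__(self, x: Tensor) -> Tensor:
        h = self.conv1(relu(self.norm1(x)))
        h = self.conv2(relu(self.norm2(h)))
        shortcut = self.proj(x) if self.proj is not None else x
        from .tensor import add
        return add(h, shortcut)
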