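"""Parameterized building blocks (modules) over the autodiff tensors."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = ["Module", "Parameter", "Linear", "Conv2d", "Conv3d", "LayerNorm", "InstanceNorm"]

DTYPE = np.float32


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True)


class Module:
    """Base class: children and parameters are discovered via attributes."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        self._collect(params, seen)
        return params

    def _collect(self, params, seen):
        for value in vars(self).values():
            self._visit(value, params, seen)

    @staticmethod
    def _visit(value, params, seen):
        if isinstance(value, Parameter):
            if id(value) not in seen:
                seen.add(id(value))
                params.append(value)
        elif isinstance(value, Module):
            value._collect(params, seen)
        elif isinstance(value, (list, tuple)):
            for v in value:
                Module._visit(v, params, seen)
        elif isinstance(value, dict):
            for v in value.values():
                Module._visit(v, params, seen)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(f"state has {len(state)} arrays, module has {len(params)} parameters")
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"], dtype=DTYPE)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for parameter {i}: {arr.shape} vs {p.data.shape}")
            p.data = arr

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(DTYPE)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, bias: bool = True):
        self.weight = Parameter(_kaiming(rng, (in_dim, out_dim), in_dim))
        self.bias = Parameter(np.zeros(out_dim)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator, kernel: int = 3):
        fan_in = cin * kernel * kernel
        self.weight = Parameter(_kaiming(rng, (cout, cin, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(cout))

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias)


class Conv3d(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator, kernel: int = 3):
        fan_in = cin * kernel**3
        self.weight = Parameter(_kaiming(rng, (cout, cin, kernel, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(cout))

    def forward(self, x: Tensor) -> Tensor:
        return F.conv3d(x, self.weight, self.bias)


class LayerNorm(Module):
    def __init__(self, dim: int, axis: int = -1):
        self.gain = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))
        self.axis = axis

    def forward(self, x: Tensor) -> Tensor:
        return F.layer_norm(x, self.gain, self.bias, axis=self.axis)


class InstanceNorm(Module):
    def __init__(self, channels: int):
        self.gain = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))

    def forward(self, x: Tensor) -> Tensor:
        return F.instance_norm(x, self.gain, self.bias)
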