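"""Neural-network layers built on the autodiff engine.

Mirrors the familiar Module/Parameter idiom: layers register parameters and
sub-modules automatically through ``__setattr__``, expose ``state_dict`` /
``load_state_dict`` for checkpointing, and switch between training and
evaluation behaviour with ``train()`` / ``eval()`` (batch normalization is
the only layer that cares).

A lightweight profiler hook lets the architecture module account parameters
and multiply–accumulate operations per layer from a real forward pass:
inside :func:`profiling`, every ``Conv2d``/``Linear`` forward appends an
exact MAC count for the shapes it actually saw.
"""

from __future__ import annotations

from contextlib import contextmanager
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, batch_norm2d, conv2d, max_pool2d

__all__ = [
    "Parameter", "Module", "Sequential", "Conv2d", "Linear", "BatchNorm2d",
    "ReLU", "MaxPool2d", "manual_seed", "profiling", "MacRecord",
]

_INIT_RNG = np.random.default_rng(0)


def manual_seed(seed: int) -> None:
    """Reseed the generator used for parameter initialization."""
    global _INIT_RNG
    _INIT_RNG = np.random.default_rng(seed)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


@dataclass
class MacRecord:
    name: str
    macs: int
    out_shape: tuple[int, ...]


_PROFILE: list[MacRecord] | None = None


@contextmanager
def profiling():
    """Collect per-layer MAC records from forward passes run inside."""
    global _PROFILE
    prev = _PROFILE
    _PROFILE = []
    try:
        yield _PROFILE
    finally:
        _PROFILE = prev


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)
        object.__setattr__(self, "_prof_name", type(self).__name__)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal -----------------------------------------------------------
    def named_modules(self, prefix: str = ""):
        yield prefix or type(self).__name__.lower(), self
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_modules(sub)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield (f"{prefix}.{name}" if prefix else name), p
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_parameters(sub)

    def named_buffers(self, prefix: str = ""):
        for name, b in self._buffers.items():
            yield (f"{prefix}.{name}" if prefix else name), b
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_buffers(sub)

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    # -- checkpointing ---------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            src = np.asarray(state[name], dtype=np.float32)
            if src.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: "
                                 f"{src.shape} vs {p.data.shape}")
            p.data[...] = src
        for name, b in self.named_buffers():
            b[...] = np.asarray(state[name], dtype=b.dtype)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            self._modules[str(i)] = layer

    def __iter__(self):
        return iter(self.layers)

    def __getitem__(self, i):
        return self.layers[i]

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


def _he_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    bound = float(np.sqrt(6.0 / fan_in))
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 padding: int = 0, stride: int = 1, bias: bool = True):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.padding = padding
        self.stride = stride
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(_he_uniform(
            _INIT_RNG, (out_channels, in_channels, kernel_size, kernel_size), fan_in))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = conv2d(x, self.weight, self.bias,
                     stride=self.stride, padding=self.padding)
        if _PROFILE is not None:
            n, _, oh, ow = out.shape
            macs = n * oh * ow * self.out_channels * self.in_channels * self.kernel_size ** 2
            _PROFILE.append(MacRecord(self._prof_name, macs, out.shape))
        return out


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(_he_uniform(
            _INIT_RNG, (in_features, out_features), in_features))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        if _PROFILE is not None:
            n = int(np.prod(out.shape[:-1]))
            _PROFILE.append(MacRecord(
                self._prof_name, n * self.in_features * self.out_features, out.shape))
        return out


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_features, dtype=np.float32))
        self.bias = Parameter(np.zeros(num_features, dtype=np.float32))
        self.register_buffer("running_mean", np.zeros(num_features, dtype=np.float32))
        self.register_buffer("running_var", np.ones(num_features, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return batch_norm2d(x, self.weight, self.bias,
                            self.running_mean, self.running_var,
                            training=self.training,
                            momentum=self.momentum, eps=self.eps)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class MaxPool2d(Module):
    def __init__(self, kernel_size: int = 2):
        super().__init__()
        self.kernel_size = kernel_size

    def forward(self, x: Tensor) -> Tensor:
        return max_pool2d(x, self.kernel_size)
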