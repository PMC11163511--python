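"""Neural-network layers built on the autodiff tensor.

Layers follow the usual NCHW convention.  Every layer that owns weights
takes a ``numpy.random.Generator`` so model construction is fully
deterministic under a seed.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Module:
    """Base class: parameter/buffer registration, mode flags, state dicts."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def _set_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal -----------------------------------------------------------
    def named_modules(self, prefix: str = "") -> Iterator[tuple[str, "Module"]]:
        yield prefix, self
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_modules(sub)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, p in self._params.items():
            yield (f"{prefix}.{name}" if prefix else name), p
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_parameters(sub)

    def parameters(self) -> Iterator[Tensor]:
        for _, p in self.named_parameters():
            yield p

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    # -- modes ---------------------------------------------------------------
    def train(self, mode: bool = True) -> "Module":
        object.__setattr__(self, "training", mode)
        for mod in self._modules.values():
            mod.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- serialization -------------------------------------------------------
    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, p in self._params.items():
            out[f"{prefix}{name}"] = p.data.copy()
        for name, buf in self._buffers.items():
            out[f"{prefix}{name}"] = np.array(buf, copy=True)
        for name, mod in self._modules.items():
            out.update(mod.state_dict(f"{prefix}{name}."))
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, p in self._params.items():
            key = f"{prefix}{name}"
            if key not in state:
                raise KeyError(f"missing parameter '{key}' in state dict")
            arr = np.asarray(state[key], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for '{key}': "
                    f"checkpoint {arr.shape} vs model {p.data.shape}")
            p.data = arr.copy()
        for name in self._buffers:
            key = f"{prefix}{name}"
            if key in state:
                self._set_buffer(name, np.array(state[key], copy=True))
        for name, mod in self._modules.items():
            mod.load_state_dict(state, f"{prefix}{name}.")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


def parameter(data: np.ndarray) -> Tensor:
    t = Tensor(data)
    t.requires_grad = True
    return t


class Conv2d(Module):
    """2-D convolution; He-normal weight init (fan-in of the kernel)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1, padding: int | None = None,
                 bias: bool = True, init_scale: float | None = None):
        super().__init__()
        if padding is None:
            padding = kernel_size // 2
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel_size * kernel_size
        std = init_scale if init_scale is not None else np.sqrt(2.0 / fan_in)
        self.weight = parameter(
            rng.normal(0.0, std, (out_channels, in_channels, kernel_size, kernel_size)))
        self.bias = parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return T.conv2d(x, self.weight, self.bias,
                        stride=self.stride, padding=self.padding)


class Linear(Module):
    """Affine map on the last axis; weight stored (in, out)."""

    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True,
                 init_scale: float | None = None):
        super().__init__()
        std = init_scale if init_scale is not None else np.sqrt(1.0 / in_features)
        self.weight = parameter(rng.normal(0.0, std, (in_features, out_features)))
        self.bias = parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = T.matmul(x, self.weight)
        if self.bias is not None:
            y = T.add(y, self.bias)
        return y


class GroupNorm(Module):
    def __init__(self, num_groups: int, num_channels: int, eps: float = 1e-5):
        super().__init__()
        if num_channels % num_groups:
            raise ValueError(
                f"GroupNorm: {num_groups} groups do not divide {num_channels} channels")
        self.num_groups = num_groups
        self.num_channels = num_channels
        self.eps = eps
        self.gamma = parameter(np.ones(num_channels))
        self.beta = parameter(np.zeros(num_channels))

    def forward(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        g = self.num_groups
        xg = T.reshape(x, (b, g, c // g * h * w))
        mu = T.tmean(xg, axis=2, keepdims=True)
        xc = xg - mu
        var = T.tmean(T.mul(xc, xc), axis=2, keepdims=True)
        xn = xc * T.power(var + self.eps, -0.5)
        xn = T.reshape(xn, (b, c, h, w))
        return xn * T.reshape(self.gamma, (1, c, 1, 1)) \
            + T.reshape(self.beta, (1, c, 1, 1))


class BatchNorm2d(Module):
    def __init__(self, num_channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_channels = num_channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = parameter(np.ones(num_channels))
        self.beta = parameter(np.zeros(num_channels))
        self.register_buffer("running_mean", np.zeros(num_channels, dtype=np.float32))
        self.register_buffer("running_var", np.ones(num_channels, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        if self.training:
            mu = T.tmean(x, axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = T.tmean(T.mul(xc, xc), axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self._set_buffer("running_mean",
                             (1 - m) * self.running_mean + m * mu.data.reshape(c))
            self._set_buffer("running_var",
                             (1 - m) * self.running_var + m * var.data.reshape(c))
            xn = xc * T.power(var + self.eps, -0.5)
        else:
            mu = self.running_mean.reshape(1, c, 1, 1)
            sd = np.sqrt(self.running_var.reshape(1, c, 1, 1) + self.eps)
            xn = (x - Tensor(mu)) * Tensor(1.0 / sd)
        return xn * T.reshape(self.gamma, (1, c, 1, 1)) \
            + T.reshape(self.beta, (1, c, 1, 1))


class LayerNorm(Module):
    """Normalisation over the last axis (token feature dimension)."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.dim = dim
        self.eps = eps
        self.gamma = parameter(np.ones(dim))
        self.beta = parameter(np.zeros(dim))

    def forward(self, x: Tensor) -> Tensor:
        mu = T.tmean(x, axis=-1, keepdims=True)
        xc = x - mu
        var = T.tmean(T.mul(xc, xc), axis=-1, keepdims=True)
        xn = xc * T.power(var + self.eps, -0.5)
        return xn * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator | None = None):
        super().__init__()
        self.p = p
        self.rng = rng if rng is not None else np.random.default_rng(0)

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * Tensor(mask)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return T.relu(x)


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)
        self._order = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self._order:
            x = m(x)
        return x


class ModuleList(Module):
    def __init__(self, mods: list[Module]):
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)
        self._items = list(mods)

    def __iter__(self):
        return iter(self._items)

    def __len__(self):
        return len(self._items)

    def __getitem__(self, i):
        return self._items[i]


NORM_TYPES = (GroupNorm, BatchNorm2d, LayerNorm)
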