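"""Layers and module containers built on :mod:`petseg.nn.tensor`.

Parameters are float32. Initialisation is He-normal (fan-in) driven by an
explicit ``numpy.random.Generator`` so that model construction is
reproducible from a seed.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .tensor import (Tensor, concat, conv_depthwise2d, conv_nd, maxpool2d,
                     upsample_nearest)

__all__ = [
    "Module", "ModuleList", "Sequential",
    "Conv2d", "Conv3d", "DepthwiseConv2d", "BatchNorm",
    "MaxPool2d", "Upsample",
]


class Module:
    """Base class: parameter/buffer registration, train/eval mode, state dict."""

    def __init__(self):
        self.training = True
        self._buffers: dict[str, np.ndarray] = {}

    # -- forward -------------------------------------------------------------
    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    # -- traversal -----------------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, value in vars(self).items():
            if name.startswith("_") or name == "training":
                continue
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, value in self._buffers.items():
            yield f"{prefix}{name}", value
        for name, value in vars(self).items():
            if name.startswith("_") or name == "training":
                continue
            full = f"{prefix}{name}"
            if isinstance(value, Module):
                yield from value.named_buffers(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{full}.{i}.")

    def modules(self) -> Iterator["Module"]:
        yield self
        for name, value in vars(self).items():
            if name.startswith("_"):
                continue
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    # -- mode ----------------------------------------------------------------
    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    # -- checkpointing -------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param:{n}": p.data.copy() for n, p in self.named_parameters()}
        state.update({f"buffer:{n}": b.copy() for n, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for key, arr in state.items():
            kind, name = key.split(":", 1)
            if kind == "param":
                if name not in params:
                    raise KeyError(f"unknown parameter {name!r}")
                if params[name].data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {name!r}")
                params[name].data = arr.astype(params[name].data.dtype).copy()
            else:
                self._set_buffer(name, arr)

    def _set_buffer(self, dotted: str, arr: np.ndarray) -> None:
        obj: Module = self
        parts = dotted.split(".")
        for part in parts[:-1]:
            if part.isdigit():
                obj = obj[int(part)]  # type: ignore[index]
            else:
                obj = getattr(obj, part)
        obj._buffers[parts[-1]] = arr.copy()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class ModuleList(Module):
    def __init__(self, items=()):
        super().__init__()
        self.items = list(items)

    def __iter__(self):
        return iter(self.items)

    def __len__(self):
        return len(self.items)

    def __getitem__(self, i):
        return self.items[i]

    def append(self, m: Module) -> None:
        self.items.append(m)


class Sequential(ModuleList):
    def forward(self, x: Tensor) -> Tensor:
        for m in self.items:
            x = m(x)
        return x


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> Tensor:
    std = np.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, std, size=shape).astype(np.float32),
                  requires_grad=True)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, kernel: int = 3, *, stride: int = 1,
                 dilation: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride = stride
        self.dilation = dilation
        self.weight = _he_init(rng, (cout, cin, kernel, kernel), cin * kernel * kernel)
        self.bias = Tensor(np.zeros(cout, np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv_nd(x, self.weight, self.bias, stride=self.stride,
                       dilation=self.dilation)


class Conv3d(Module):
    def __init__(self, cin: int, cout: int, kernel: int = 3, *, stride: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride = stride
        self.weight = _he_init(rng, (cout, cin, kernel, kernel, kernel),
                               cin * kernel ** 3)
        self.bias = Tensor(np.zeros(cout, np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv_nd(x, self.weight, self.bias, stride=self.stride)


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, kernel: int = 3, *, dilation: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.dilation = dilation
        self.weight = _he_init(rng, (channels, kernel, kernel), kernel * kernel)

    def forward(self, x: Tensor) -> Tensor:
        return conv_depthwise2d(x, self.weight, dilation=self.dilation)


class BatchNorm(Module):
    """Batch normalisation over batch + spatial axes (2D or 3D feature maps).

    ``zero_init`` starts the affine gain at 0; placed on the last norm of a
    residual branch this makes the block an identity at initialisation, so
    deep residual stacks start with controlled activation variance instead
    of saturating the output sigmoid (which would stall training through
    vanishing clipped-log gradients).
    """

    def __init__(self, channels: int, *, eps: float = 1e-5, momentum: float = 0.1,
                 zero_init: bool = False):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        init = 0.0 if zero_init else 1.0
        self.gamma = Tensor(np.full(channels, init, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, np.float32), requires_grad=True)
        self._buffers["running_mean"] = np.zeros(channels, np.float32)
        self._buffers["running_var"] = np.ones(channels, np.float32)

    def forward(self, x: Tensor) -> Tensor:
        nd = x.ndim - 2
        shape = (1, -1) + (1,) * nd
        axes = (0,) + tuple(range(2, x.ndim))
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) * (x - mu)).mean(axis=axes, keepdims=True)
            m = self.momentum
            self._buffers["running_mean"] = (
                (1 - m) * self._buffers["running_mean"]
                + m * mu.data.reshape(-1).astype(np.float32))
            self._buffers["running_var"] = (
                (1 - m) * self._buffers["running_var"]
                + m * var.data.reshape(-1).astype(np.float32))
            inv = (var + self.eps).pow(-0.5)
            y = (x - mu) * inv
            return y * self.gamma.reshape(shape) + self.beta.reshape(shape)
        # eval: fold running stats + affine into one scale/shift pair
        rm = self._buffers["running_mean"]
        rv = self._buffers["running_var"]
        scale = (self.gamma.data / np.sqrt(rv + self.eps)).reshape(shape)
        shift = (self.beta.data - rm * scale.reshape(-1)).reshape(shape)
        return x * Tensor(scale.astype(x.data.dtype)) + Tensor(shift.astype(x.data.dtype))


class MaxPool2d(Module):
    def forward(self, x: Tensor) -> Tensor:
        return maxpool2d(x)


class Upsample(Module):
    def forward(self, x: Tensor) -> Tensor:
        return upsample_nearest(x)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


__all__ += ["ReLU", "Sigmoid"]
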