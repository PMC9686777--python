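"""Small layer library on top of the autodiff engine.

Weight layout conventions match the usual deep-learning ones:
``Conv1d`` weight is (out_channels, in_channels, kernel), ``ConvTranspose1d``
weight is (in_channels, out_channels, kernel), depthwise variants carry one
kernel per channel as (channels, kernel).  Modules discover their trainable
tensors recursively through attributes, lists of modules, and sub-modules.
"""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Parameter, Tensor

__all__ = [
    "Module",
    "Conv1d",
    "ConvTranspose1d",
    "DepthwiseConv1d",
    "DepthwiseConvTranspose1d",
    "ChannelLayerNorm",
]


class Module:
    """Base class with recursive parameter discovery."""

    def named_parameters(self, prefix: str = ""):
        out = []
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                out.append((prefix + name, value))
            elif isinstance(value, Module):
                out.extend(value.named_parameters(prefix + name + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(f"{prefix}{name}.{i}."))
        return out

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def n_params(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(
                f"state dict mismatch: missing={sorted(missing)}, "
                f"unexpected={sorted(extra)}"
            )
        for name, p in own.items():
            arr = np.asarray(state[name])
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}"
                )
            p.data = arr.astype(p.data.dtype)

    def astype(self, dtype) -> "Module":
        for p in self.parameters():
            p.data = p.data.astype(dtype)
        return self


def _init(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    scale = math.sqrt(1.0 / fan_in)
    return (rng.standard_normal(shape) * scale).astype(dtype)


class Conv1d(Module):
    def __init__(self, cin, cout, kernel, stride=1, bias=True, *,
                 rng: np.random.Generator, dtype=np.float32):
        self.stride = stride
        self.weight = Parameter(_init(rng, (cout, cin, kernel), cin * kernel, dtype))
        self.bias = Parameter(np.zeros(cout, dtype=dtype)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv1d(self.weight, self.bias, self.stride)


class ConvTranspose1d(Module):
    def __init__(self, cin, cout, kernel, stride=1, bias=True, *,
                 rng: np.random.Generator, dtype=np.float32):
        self.stride = stride
        self.weight = Parameter(_init(rng, (cin, cout, kernel), cin * kernel, dtype))
        self.bias = Parameter(np.zeros(cout, dtype=dtype)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv_transpose1d(self.weight, self.bias, self.stride)


class DepthwiseConv1d(Module):
    def __init__(self, channels, kernel, stride=1, bias=True, *,
                 rng: np.random.Generator, dtype=np.float32):
        self.stride = stride
        self.weight = Parameter(_init(rng, (channels, kernel), kernel, dtype))
        self.bias = Parameter(np.zeros(channels, dtype=dtype)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return x.dwconv1d(self.weight, self.bias, self.stride)


class DepthwiseConvTranspose1d(Module):
    def __init__(self, channels, kernel, stride=1, bias=True, *,
                 rng: np.random.Generator, dtype=np.float32):
        self.stride = stride
        self.weight = Parameter(_init(rng, (channels, kernel), kernel, dtype))
        self.bias = Parameter(np.zeros(channels, dtype=dtype)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return x.dwconv_transpose1d(self.weight, self.bias, self.stride)


class ChannelLayerNorm(Module):
    """Layer norm over the channel axis (axis 1) with per-channel gain/offset.

    Normalizing per position keeps the operation independent of sequence
    length, so the same weights serve chunks of any K or S.  The epsilon
    guard maps an all-zero input to the (zero-initialized) offset.
    """

    def __init__(self, channels, eps: float = 1e-5, *, dtype=np.float32):
        self.eps = eps
        self.gain = Parameter(np.ones((channels, 1), dtype=dtype))
        self.offset = Parameter(np.zeros((channels, 1), dtype=dtype))

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=1, keepdims=True)
        xn = xc / (var + self.eps).sqrt()
        return xn * self.gain + self.offset
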