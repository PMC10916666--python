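"""Neural-network layers built on the autodiff engine.

Initialisation follows the image-translation convention of zero-mean normal
weights with standard deviation 0.02; every parameterised layer takes an
explicit ``numpy.random.Generator`` so construction is reproducible.
"""

from __future__ import annotations

import numpy as np

from . import tensor as F
from .tensor import Tensor

INIT_STD = 0.02


class Module:
    """Base class: nested parameter discovery and flat state dicts."""

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            path = f"{prefix}{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                yield path, val
            elif isinstance(val, Module):
                yield from val.named_parameters(prefix=path + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{path}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for name, p in params.items():
            p.data = np.asarray(state[name], dtype=p.data.dtype).reshape(p.shape)

    def __call__(self, x):
        return self.forward(x)

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Conv2d(Module):
    """2-D convolution with optional zero/reflection padding."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng,
                 stride: int = 1, padding: int = 0, pad_mode: str = "zeros",
                 bias: bool = True):
        self.stride = stride
        self.padding = padding
        self.pad_mode = pad_mode
        self.weight = Tensor(
            rng.normal(0.0, INIT_STD, size=(out_ch, in_ch, kernel, kernel)),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None

    def forward(self, x):
        if self.padding:
            p = self.padding
            x = F.pad2d(x, (p, p, p, p), mode=self.pad_mode)
        return F.conv2d(x, self.weight, self.bias, stride=self.stride)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng):
        self.weight = Tensor(
            rng.normal(0.0, INIT_STD, size=(in_features, out_features)),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def forward(self, x):
        return x @ self.weight + self.bias


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalisation over the spatial axes.

    Suits style transfer, where statistics of individual images matter and
    batch statistics would blur per-sample detail.
    """

    def __init__(self, num_channels: int, eps: float = 1e-5, affine: bool = True):
        self.eps = eps
        if affine:
            self.gamma = Tensor(np.ones((1, num_channels, 1, 1)), requires_grad=True)
            self.beta = Tensor(np.zeros((1, num_channels, 1, 1)), requires_grad=True)
        else:
            self.gamma = self.beta = None

    def forward(self, x):
        return F.instance_norm(x, self.gamma, self.beta, self.eps)


class ReLU(Module):
    def forward(self, x):
        return F.relu(x)


class LeakyReLU(Module):
    def __init__(self, alpha: float = 0.2):
        self.alpha = alpha

    def forward(self, x):
        return F.leaky_relu(x, self.alpha)


class Tanh(Module):
    def forward(self, x):
        return F.tanh(x)


class ResnetBlock(Module):
    """Residual block: two reflection-padded 3x3 convolutions with
    instance normalisation, identity skip connection."""

    def __init__(self, dim: int, rng):
        self.conv1 = Conv2d(dim, dim, 3, rng, padding=1, pad_mode="reflect")
        self.norm1 = InstanceNorm2d(dim)
        self.conv2 = Conv2d(dim, dim, 3, rng, padding=1, pad_mode="reflect")
        self.norm2 = InstanceNorm2d(dim)

    def forward(self, x):
        h = F.relu(self.norm1(self.conv1(x)))
        h = self.norm2(self.conv2(h))
        return x + h
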