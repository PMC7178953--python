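"""Trainable layer objects on top of the autograd engine.

Weight initialization follows the adaptive-Gaussian rule used throughout
the network: weights are drawn from N(0, std^2) with
std = sqrt(2 / ((2r+1)^2 * c_in)), the He-style standard deviation for a
(2r+1)x(2r+1) kernel over c_in input channels.  Biases start at zero,
batch-norm at scale 1 / shift 0.
"""

from __future__ import annotations

import math

import numpy as np

from . import autograd as ag
from .autograd import Tensor

DTYPE = np.float32


def init_std(r: int, c_in: int) -> float:
    """Initialization standard deviation sqrt(2 / ((2r+1)^2 * c_in))."""
    if c_in <= 0:
        raise ValueError(f"c_in must be positive, got {c_in}")
    if r < 0:
        raise ValueError(f"kernel radius must be >= 0, got {r}")
    return math.sqrt(2.0 / ((2 * r + 1) ** 2 * c_in))


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True)


class Module:
    """Base class: recursive parameter collection and train/eval mode."""

    def __init__(self):
        self.training = False

    def modules(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item
                        yield from item.modules()

    def parameters(self):
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                yield v
        for m in self.modules():
            for v in m.__dict__.values():
                if isinstance(v, Parameter):
                    yield v

    def named_parameters(self, prefix=""):
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Parameter):
                yield name, v
            elif isinstance(v, Module):
                yield from v.named_parameters(name + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{name}.{i}.")

    def buffers(self, prefix=""):
        """Non-trainable state (batch-norm running statistics)."""
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, np.ndarray):
                yield name, v
            elif isinstance(v, Module):
                yield from v.buffers(name + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.buffers(f"{name}.{i}.")

    def train(self, mode=True):
        self.training = mode
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def count_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class Conv2d(Module):
    """Stride-1 same-resolution convolution, optionally dilated."""

    def __init__(self, c_in, c_out, kernel_size, dilation=1, bias=True, rng=None):
        super().__init__()
        if dilation < 1:
            raise ValueError(f"dilation factor must be >= 1, got {dilation}")
        rng = rng if rng is not None else np.random.default_rng()
        r = kernel_size // 2
        std = init_std(r, c_in)
        self.dilation = int(dilation)
        self.weight = Parameter(rng.normal(0.0, std, (c_out, c_in, kernel_size, kernel_size)))
        self.bias = Parameter(np.zeros(c_out)) if bias else None

    def __call__(self, x):
        return ag.conv2d(x, self.weight, self.bias, dilation=self.dilation)


class ConvTranspose2d(Module):
    """3x3 stride-2 transposed convolution; doubles spatial dims."""

    def __init__(self, c_in, c_out, bias=True, rng=None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng()
        std = init_std(1, c_in)
        self.weight = Parameter(rng.normal(0.0, std, (c_in, c_out, 3, 3)))
        self.bias = Parameter(np.zeros(c_out)) if bias else None

    def __call__(self, x):
        return ag.conv_transpose2d(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, channels, momentum=0.9, eps=1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x):
        return ag.batch_norm2d(x, self.gamma, self.beta, self.running_mean,
                               self.running_var, self.training,
                               momentum=self.momentum, eps=self.eps)


class RMSProp:
    """RMSProp with decay 0.9 and epsilon 1e-8, no momentum."""

    def __init__(self, params, lr, decay=0.9, eps=1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.decay = decay
        self.eps = eps
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self.v):
            if p.grad is None:
                continue
            g = p.grad
            v *= self.decay
            v += (1 - self.decay) * g * g
            p.data -= self.lr * g / (np.sqrt(v) + self.eps)
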