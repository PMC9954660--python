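"""Layer modules on top of the autodiff engine.

Mirrors the familiar Module/parameters()/train()/eval() surface of the large
frameworks at the scale this package needs.  Parameters are He/Glorot
initialised from a caller-supplied generator so builds are reproducible.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["Module", "Conv2d", "ConvTranspose2x2", "BatchNorm2d",
           "ReLU", "Sigmoid", "MaxPool2x2", "Sequential"]


class Module:
    """Base class: child modules and parameters discovered via attributes."""

    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix=""):
        for name, v in self.__dict__.items():
            if isinstance(v, Tensor) and v.requires_grad:
                yield f"{prefix}{name}", v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{prefix}{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- flat state dict of ndarrays (includes batch-norm running stats) --
    def state_dict(self):
        state = {}
        for name, p in self.named_parameters():
            state[name] = p.data.copy()
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                state[f"__bn{i}.running_mean"] = m.running_mean.copy()
                state[f"__bn{i}.running_var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state):
        for name, p in self.named_parameters():
            p.data[...] = state[name]
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                m.running_mean[...] = state[f"__bn{i}.running_mean"]
                m.running_var[...] = state[f"__bn{i}.running_var"]


class Conv2d(Module):
    """Stride-1 convolution with 'same' zero padding and He-normal init.

    `bias=False` is used for convolutions immediately followed by batch
    normalisation, where the BN shift makes a bias redundant.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(rng.normal(0.0, std, (out_ch, in_ch, kernel, kernel)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None

    def forward(self, x):
        return ad.conv2d(x, self.weight, self.bias)


class ConvTranspose2x2(Module):
    """Learnable 2x upsampling: transposed conv, kernel 2, stride 2."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(2.0 / (in_ch * 4))
        self.weight = Tensor(rng.normal(0.0, std, (in_ch, out_ch, 2, 2)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)

    def forward(self, x):
        return ad.conv_transpose2d_2x2(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x):
        return ad.batchnorm2d(x, self.gamma, self.beta, self.running_mean,
                              self.running_var, self.training,
                              self.momentum, self.eps)


class ReLU(Module):
    def forward(self, x):
        return ad.relu(x)


class Sigmoid(Module):
    def forward(self, x):
        return ad.sigmoid(x)


class MaxPool2x2(Module):
    def forward(self, x):
        return ad.maxpool2d_2x2(x)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x
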