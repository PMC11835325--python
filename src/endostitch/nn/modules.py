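"""Layers, parameter containers and the Adam optimizer."""

from __future__ import annotations

import numpy as np

from .core import Tensor
from . import ops

__all__ = ["Parameter", "Module", "Conv2d", "ConvTranspose2d", "Linear", "Adam"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Tiny parameter container with recursive discovery over attributes."""

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Parameter):
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{full}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise ValueError(f"state dict mismatch, differing keys: {sorted(missing)}")
        for k, p in own.items():
            arr = np.asarray(state[k], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data[...] = arr

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())


class Conv2d(Module):
    def __init__(self, cin, cout, k=3, stride=1, pad=None, rng=None, zero_init=False):
        self.stride = stride
        self.pad = k // 2 if pad is None else pad
        if zero_init:
            w = np.zeros((cout, cin, k, k))
        else:
            rng = rng or np.random.default_rng()
            # He initialisation for ReLU-family activations
            w = rng.normal(0.0, np.sqrt(2.0 / (cin * k * k)), size=(cout, cin, k, k))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(cout))

    def __call__(self, x: Tensor) -> Tensor:
        return ops.conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class ConvTranspose2d(Module):
    """Fixed geometry: kernel 4, stride 2, pad 1 → exact 2x upsampling."""

    def __init__(self, cin, cout, rng=None):
        rng = rng or np.random.default_rng()
        w = rng.normal(0.0, np.sqrt(2.0 / (cin * 16)), size=(cin, cout, 4, 4))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(cout))

    def __call__(self, x: Tensor) -> Tensor:
        return ops.conv_transpose2d(x, self.weight, self.bias)


class Linear(Module):
    def __init__(self, nin, nout, rng=None, zero_init=False):
        if zero_init:
            w = np.zeros((nin, nout))
        else:
            rng = rng or np.random.default_rng()
            w = rng.normal(0.0, np.sqrt(2.0 / nin), size=(nin, nout))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(nout))

    def __call__(self, x: Tensor) -> Tensor:
        return x.matmul(self.weight) + self.bias


class Adam:
    """Adam with optional per-step exponential learning-rate decay."""

    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
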