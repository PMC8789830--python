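"""Minimal neural-network building blocks on top of the autodiff engine.

Layers follow the conventions of the reconstruction networks: He-normal
weight initialization, PReLU with a trainable per-channel leakage,
batch normalization for the discriminator, and an Adam optimizer with
classic L2 weight decay.
"""

from __future__ import annotations

import numpy as np

from ._autograd import Tensor

__all__ = ["Module", "Conv2d", "PReLU", "BatchNorm2d", "Adam", "he_normal"]


def he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Module:
    """Base class; collects parameters from attributes recursively."""

    def parameters(self) -> list[Tensor]:
        params, seen = [], set()
        for value in vars(self).values():
            items = value if isinstance(value, (list, tuple)) else [value]
            for item in items:
                if isinstance(item, Tensor) and item.requires_grad:
                    if id(item) not in seen:
                        seen.add(id(item))
                        params.append(item)
                elif isinstance(item, Module):
                    for p in item.parameters():
                        if id(p) not in seen:
                            seen.add(id(p))
                            params.append(p)
        return params

    def modules(self) -> list["Module"]:
        mods = [self]
        for value in vars(self).values():
            items = value if isinstance(value, (list, tuple)) else [value]
            for item in items:
                if isinstance(item, Module):
                    mods.extend(item.modules())
        return mods

    def train(self):
        for m in self.modules():
            m._training = True

    def eval(self):
        for m in self.modules():
            m._training = False

    def state_arrays(self) -> list[np.ndarray]:
        """All parameter arrays plus any buffers, for checkpointing."""
        arrays = [p.data for p in self.parameters()]
        for m in self.modules():
            arrays.extend(getattr(m, "_buffers", []))
        return arrays

    def load_state_arrays(self, arrays):
        arrays = list(arrays)
        params = self.parameters()
        for p, a in zip(params, arrays[: len(params)]):
            if p.data.shape != a.shape:
                raise ValueError("checkpoint shape mismatch")
            p.data = np.asarray(a, dtype=np.float64)
        rest = arrays[len(params):]
        for m in self.modules():
            bufs = getattr(m, "_buffers", [])
            for i in range(len(bufs)):
                bufs[i][...] = rest.pop(0)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng,
                 stride: int = 1, bias: bool = True, bias_init: float = 0.0):
        pad = (kernel - 1) // 2
        fan_in = in_ch * kernel * kernel
        self.weight = Tensor(he_normal(rng, (out_ch, in_ch, kernel, kernel), fan_in),
                             requires_grad=True)
        self.bias = (Tensor(np.full(out_ch, bias_init), requires_grad=True)
                     if bias else None)
        self.stride = stride
        self.padding = pad

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride,
                        padding=self.padding)


class PReLU(Module):
    def __init__(self, channels: int, init: float = 0.25):
        self.alpha = Tensor(np.full(channels, init), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.prelu(self.alpha)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.momentum = momentum
        self.eps = eps
        self._training = True
        self._buffers = [np.zeros(channels), np.ones(channels)]  # mean, var

    def __call__(self, x: Tensor) -> Tensor:
        run_mean, run_var = self._buffers
        if self._training:
            mu = x.mean(axis=0, keepdims=True).mean(axis=2, keepdims=True) \
                  .mean(axis=3, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=0, keepdims=True) \
                .mean(axis=2, keepdims=True).mean(axis=3, keepdims=True)
            run_mean[...] = (1 - self.momentum) * run_mean \
                + self.momentum * mu.data.ravel()
            run_var[...] = (1 - self.momentum) * run_var \
                + self.momentum * var.data.ravel()
        else:
            mu = Tensor(run_mean.reshape(1, -1, 1, 1))
            var = Tensor(run_var.reshape(1, -1, 1, 1))
        xn = (x - mu) / ((var + self.eps).sqrt())
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xn * g + b


class Adam:
    """Adam with optional classic L2 penalty added to the gradient."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8, l2: float = 0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.l2 = lr, betas, eps, l2
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.l2:
                g = g + self.l2 * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mh = self.m[i] / (1 - b1**self.t)
            vh = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * mh / (np.sqrt(vh) + self.eps)
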