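"""Trainable layers and the Adam optimizer on top of the autograd engine."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d, depthwise_conv2d

__all__ = ["Parameter", "Module", "Conv2d", "DepthwiseConv2d", "BatchNorm2d",
           "ReLU", "ReLU6", "Sequential", "Identity", "Adam"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Container with recursive parameter discovery and train/eval modes."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in vars(self).values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = ""):
        for name, v in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(v, Parameter):
                yield full, v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{full}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, m in self._named_modules():
            if isinstance(m, BatchNorm2d):
                state[f"{name}.running_mean"] = m.running_mean.copy()
                state[f"{name}.running_var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for name, p in params.items():
            p.data = np.asarray(state[name], dtype=np.float32).reshape(p.shape)
        for name, m in self._named_modules():
            if isinstance(m, BatchNorm2d):
                m.running_mean = np.asarray(state[f"{name}.running_mean"],
                                            dtype=np.float32)
                m.running_var = np.asarray(state[f"{name}.running_var"],
                                           dtype=np.float32)

    def _named_modules(self, prefix: str = ""):
        for name, v in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(v, Module):
                yield full, v
                yield from v._named_modules(f"{full}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield f"{full}.{i}", item
                        yield from item._named_modules(f"{full}.{i}.")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel_size, stride: int = 1,
                 padding=0, dilation: int = 1, bias: bool = False,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        kh, kw = ((kernel_size, kernel_size) if isinstance(kernel_size, int)
                  else kernel_size)
        self.stride, self.padding, self.dilation = stride, padding, dilation
        fan_in = in_ch * kh * kw
        self.weight = Parameter(_kaiming(rng, (out_ch, in_ch, kh, kw), fan_in))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding, dilation=self.dilation)


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, kernel_size: int = 3, stride: int = 1,
                 padding: int = 1, dilation: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = kernel_size * kernel_size
        self.stride, self.padding, self.dilation = stride, padding, dilation
        self.weight = Parameter(
            _kaiming(rng, (channels, kernel_size, kernel_size), fan_in))

    def forward(self, x: Tensor) -> Tensor:
        return depthwise_conv2d(x, self.weight, stride=self.stride,
                                padding=self.padding, dilation=self.dilation)


class BatchNorm2d(Module):
    """Batch normalization with trainable affine and running statistics."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(channels, dtype=np.float32))
        self.bias = Parameter(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if self.training:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = (x.data - mu[None, :, None, None]) * inv[None, :, None, None]
        out_data = (xhat * self.weight.data[None, :, None, None]
                    + self.bias.data[None, :, None, None])
        gamma, beta = self.weight, self.bias
        training = self.training

        def backward(g):
            if gamma.requires_grad:
                gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
            if beta.requires_grad:
                beta._accumulate(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gi = g * gamma.data[None, :, None, None] * inv[None, :, None, None]
                if training:
                    mean_g = gi.mean(axis=(0, 2, 3), keepdims=True)
                    mean_gx = (gi * xhat).mean(axis=(0, 2, 3), keepdims=True)
                    x._accumulate(gi - mean_g - xhat * mean_gx)
                else:
                    x._accumulate(gi)

        out = Tensor(out_data)
        if x.requires_grad or gamma.requires_grad or beta.requires_grad:
            out.requires_grad = True
            out._prev = (x, gamma, beta)
            out._backward = backward
        return out


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class ReLU6(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu6()


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Adam:
    """Adam optimizer (Kingma & Ba) with bias-corrected moment estimates."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
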