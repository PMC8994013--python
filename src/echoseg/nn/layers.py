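"""Parameterized building blocks on top of the autodiff engine."""

from __future__ import annotations

import numpy as np

from echoseg.nn import autodiff as ad
from echoseg.nn.autodiff import Tensor


class Module:
    """Base class: recursively collects parameter tensors."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            params.extend(_collect(value))
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        return {str(i): p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(state)}")
        for i, p in enumerate(params):
            arr = np.asarray(state[str(i)])
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for parameter {i}: "
                                 f"{arr.shape} vs {p.data.shape}")
            p.data = arr.astype(p.data.dtype)


def _collect(value) -> list[Tensor]:
    if isinstance(value, Tensor) and value.requires_grad:
        return [value]
    if isinstance(value, Module):
        return value.parameters()
    if isinstance(value, (list, tuple)):
        out = []
        for v in value:
            out.extend(_collect(v))
        return out
    return []


class Conv2d(Module):
    """3x3/1x1/7x7 convolution with He-normal init and optional zero bias init."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, bias_init: float = 0.0, weight_scale: float = 1.0):
        fan_in = in_ch * kernel * kernel
        std = weight_scale * np.sqrt(2.0 / fan_in)
        self.weight = Tensor(rng.normal(0.0, std, size=(out_ch, in_ch, kernel, kernel)),
                             requires_grad=True)
        self.bias = Tensor(np.full(out_ch, bias_init), requires_grad=True)
        self.stride = stride
        self.padding = kernel // 2

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias,
                         stride=self.stride, padding=self.padding)


class ConvReLU(Module):
    def __init__(self, *args, **kwargs):
        self.conv = Conv2d(*args, **kwargs)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.relu(self.conv(x))


class BasicBlock(Module):
    """Two 3x3 convolutions with an additive shortcut (projection on resize)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 stride: int = 1):
        self.conv1 = Conv2d(in_ch, out_ch, 3, rng, stride=stride)
        self.conv2 = Conv2d(out_ch, out_ch, 3, rng, weight_scale=0.5)
        self.proj = (Conv2d(in_ch, out_ch, 1, rng, stride=stride)
                     if (stride != 1 or in_ch != out_ch) else None)

    def __call__(self, x: Tensor) -> Tensor:
        identity = self.proj(x) if self.proj is not None else x
        out = self.conv2(ad.relu(self.conv1(x)))
        return ad.relu(out + identity)


class BottleneckBlock(Module):
    """1x1 reduce -> 3x3 -> 1x1 expand (x4) with an additive shortcut."""

    expansion = 4

    def __init__(self, in_ch: int, mid_ch: int, rng: np.random.Generator,
                 stride: int = 1):
        out_ch = mid_ch * self.expansion
        self.conv1 = Conv2d(in_ch, mid_ch, 1, rng)
        self.conv2 = Conv2d(mid_ch, mid_ch, 3, rng, stride=stride)
        self.conv3 = Conv2d(mid_ch, out_ch, 1, rng, weight_scale=0.5)
        self.proj = (Conv2d(in_ch, out_ch, 1, rng, stride=stride)
                     if (stride != 1 or in_ch != out_ch) else None)

    def __call__(self, x: Tensor) -> Tensor:
        identity = self.proj(x) if self.proj is not None else x
        out = ad.relu(self.conv1(x))
        out = ad.relu(self.conv2(out))
        out = self.conv3(out)
        return ad.relu(out + identity)


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: list[Tensor], lr: float, momentum: float = 0.0):
        if lr < 0:
            raise ValueError("learning rate must be >= 0")
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self._velocity = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            v *= self.momentum
            v -= self.lr * p.grad
            p.data = p.data + v
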