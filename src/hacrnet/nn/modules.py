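"""Layer containers over the autograd engine: Conv2d, PReLU, Module."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Parameter(Tensor):
    """A leaf tensor updated by the optimizer."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Minimal module tree with named parameters and state dicts."""

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Parameter):
                yield key, val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{key}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{i}.")

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = sorted(set(own) - set(state))
        unexpected = sorted(set(state) - set(own))
        if missing or unexpected:
            raise KeyError(
                f"state dict mismatch: missing={missing[:3]} unexpected={unexpected[:3]}"
            )
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(
                    f"shape mismatch for '{k}': model {p.data.shape}, "
                    f"checkpoint {state[k].shape}"
                )
            p.data = state[k].astype(np.float32, copy=True)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """Stride-1 convolution with same-size zero padding and bias.

    Weights use Kaiming fan-in initialization with the PReLU gain
    sqrt(2 / (1 + a^2)), a = 0.25, drawn from the supplied generator so
    builds are reproducible.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        padding: int | None = None,
        bias: bool = True,
        weight_scale: float = 1.0,
        icnr_factor: int | None = None,
    ):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.padding = kernel_size // 2 if padding is None else padding
        fan_in = in_channels * kernel_size * kernel_size
        std = float(np.sqrt(2.0 / ((1.0 + 0.25**2) * fan_in)))
        if icnr_factor:
            # ICNR: r^2 sub-pixel groups share weights so a following
            # PixelShuffle starts as nearest-neighbour upsampling
            r2 = icnr_factor**2
            base = rng.normal(
                0.0, std, size=(out_channels // r2, in_channels, kernel_size, kernel_size)
            )
            w = np.repeat(base, r2, axis=0)
        else:
            w = rng.normal(
                0.0, std, size=(out_channels, in_channels, kernel_size, kernel_size)
            )
        self.weight = Parameter(w * weight_scale)
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias, self.padding)


class PReLU(Module):
    """Parametric ReLU with one learnable slope per channel (init 0.25)."""

    def __init__(self, num_channels: int, init: float = 0.25):
        self.slope = Parameter(np.full(num_channels, init))

    def forward(self, x: Tensor) -> Tensor:
        return ag.prelu(x, self.slope)


class Adam:
    """Adam with the standard bias-corrected first/second moment estimates."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * np.square(g)
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
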