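"""Network building blocks: modules, conv/BN/activation layers, containers.

Layers follow the familiar ``forward`` idiom; a module is in training mode
(``module.training``) or inference mode (``module.eval()``), which switches
batch normalization between batch and running statistics.  Initialization is
driven by an explicit ``numpy.random.Generator`` so that identical seeds give
bit-identical parameter vectors.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autodiff import Tensor, concat, conv2d, max_pool2d, upsample_nearest2d

#: parameter dtype; float32 keeps the im2col convolution cache-friendly
DTYPE = np.float32


class Module:
    """Base class: parameter discovery, train/eval mode, state dicts."""

    training: bool = True

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def children(self) -> Iterator["Module"]:
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def modules(self) -> Iterator["Module"]:
        yield self
        for child in self.children():
            yield from child.modules()

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for mod in self.modules():
            for value in mod.__dict__.values():
                if isinstance(value, Tensor) and value.requires_grad:
                    params.append(value)
        return params

    def named_state(self) -> dict[str, np.ndarray]:
        """Flat name → array mapping of all parameters and buffers."""
        state: dict[str, np.ndarray] = {}

        def visit(mod: Module, prefix: str) -> None:
            for name, value in mod.__dict__.items():
                if isinstance(value, Tensor):
                    state[f"{prefix}{name}"] = value.data
                elif isinstance(value, np.ndarray):
                    state[f"{prefix}{name}"] = value
                elif isinstance(value, Module):
                    visit(value, f"{prefix}{name}.")
                elif isinstance(value, (list, tuple)):
                    for idx, item in enumerate(value):
                        if isinstance(item, Module):
                            visit(item, f"{prefix}{name}.{idx}.")

        visit(self, "")
        return state

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        own = self.named_state()
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"state is missing entries: {sorted(missing)[:5]} ...")
        for name, arr in own.items():
            np.copyto(arr, state[name])

    def parameter_vector(self) -> np.ndarray:
        return np.concatenate([p.data.ravel() for p in self.parameters()]) \
            if self.parameters() else np.empty(0)

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def train(self) -> "Module":
        for mod in self.modules():
            mod.training = True
        return self

    def eval(self) -> "Module":
        for mod in self.modules():
            mod.training = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()


class Conv2d(Module):
    """3×3 (by default) convolution, stride 1, 'same' zero padding.

    Weights are stored channels-last, ``(kh, kw, C_in, C_out)``, matching
    the engine's image layout, and initialized He-normal in float32.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 3,
                 rng: np.random.Generator | None = None, bias: bool = True,
                 zero_init: bool = False):
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd")
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel * kernel
        scale = 0.0 if zero_init else np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            (scale * rng.standard_normal((kernel, kernel, in_channels, out_channels))
             ).astype(DTYPE),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, dtype=DTYPE), requires_grad=True) \
            if bias else None
        self.padding = kernel // 2

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, padding=self.padding)


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Tensor(np.ones(channels, dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=DTYPE), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.eps = eps
        self.momentum = momentum

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 1, 2), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 1, 2), keepdims=True)
            self.running_mean += (self.momentum *
                                  (mu.data.ravel() - self.running_mean)).astype(DTYPE)
            self.running_var += (self.momentum *
                                 (var.data.ravel() - self.running_var)).astype(DTYPE)
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        else:
            mu = self.running_mean.reshape(1, 1, 1, -1)
            var = self.running_var.reshape(1, 1, 1, -1)
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        g = self.gamma.reshape(1, 1, 1, -1)
        b = self.beta.reshape(1, 1, 1, -1)
        return xhat * g + b


class LeakyReLU(Module):
    def __init__(self, negative_slope: float = 0.2):
        self.negative_slope = negative_slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.negative_slope)


class MaxPool2d(Module):
    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x: Tensor) -> Tensor:
        return max_pool2d(x, self.size)


class UpsampleNearest2d(Module):
    def __init__(self, scale: int = 2):
        self.scale = scale

    def forward(self, x: Tensor) -> Tensor:
        return upsample_nearest2d(x, self.scale)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class ConvBlock(Module):
    """Convolution → batch norm → leaky rectifier, the basic unit of both nets."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 3,
                 negative_slope: float = 0.2, batch_norm: bool = True,
                 rng: np.random.Generator | None = None):
        self.conv = Conv2d(in_channels, out_channels, kernel, rng=rng)
        self.bn = BatchNorm2d(out_channels) if batch_norm else None
        self.act = LeakyReLU(negative_slope)

    def forward(self, x: Tensor) -> Tensor:
        x = self.conv(x)
        if self.bn is not None:
            x = self.bn(x)
        return self.act(x)


__all__ = [
    "Module", "Conv2d", "BatchNorm2d", "LeakyReLU", "MaxPool2d",
    "UpsampleNearest2d", "Sequential", "ConvBlock", "concat",
]
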