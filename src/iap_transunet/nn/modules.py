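"""Layer abstractions on top of the autodiff tape.

Mirrors the familiar ``Module`` idiom: parameters are ``Tensor``s with
``requires_grad=True`` registered as attributes; ``state_dict`` /
``load_state_dict`` round-trip plain ndarrays so checkpoints are a single
``np.savez`` archive.  All random initialisation draws from the
``np.random.Generator`` passed at construction, so a model is a pure
function of its config and seed.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .tensor import (Tensor, batch_norm2d, conv2d, layer_norm, upsample_bilinear)

__all__ = [
    "Module", "Sequential", "Identity", "ReLU", "Dropout",
    "Conv2d", "Linear", "BatchNorm2d", "GroupNorm2d", "LayerNorm", "Upsample",
]


class Module:
    def __init__(self):
        self._parameters: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    # -- registration -----------------------------------------------------
    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_parameters", {})[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal --------------------------------------------------------
    def named_modules(self, prefix: str = "") -> Iterator[tuple[str, "Module"]]:
        yield prefix, self
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_modules(sub)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, p in self._parameters.items():
            yield (f"{prefix}.{name}" if prefix else name), p
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_parameters(sub)

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, b in self._buffers.items():
            yield (f"{prefix}.{name}" if prefix else name), b
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_buffers(sub)

    # -- state ------------------------------------------------------------
    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for _, m in self._modules.items():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({f"{name}@buf": b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, value in state.items():
            if key.endswith("@buf"):
                buf = buffers[key[:-4]]
                buf[...] = value
            else:
                p = params[key]
                if p.data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {key}: "
                                     f"{p.data.shape} vs {value.shape}")
                p.data[...] = value

    # -- call -------------------------------------------------------------
    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)
        for i, m in enumerate(mods):
            self._modules[str(i)] = m

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Dropout(Module):
    """Inverted dropout; identity at p=0 or in eval mode."""

    def __init__(self, p: float = 0.0, rng: np.random.Generator | None = None):
        super().__init__()
        self.p = float(p)
        self.rng = rng or np.random.default_rng()

    def forward(self, x):
        if not self.training or self.p <= 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask.astype(np.float32))


def _kaiming_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = float(np.sqrt(6.0 / max(fan_in, 1)))
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Conv2d(Module):
    """2-d convolution with "same"-style integer padding left to the caller."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int, *,
                 stride: int = 1, padding: int | str = "same", dilation: int = 1,
                 groups: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError("channel counts must be divisible by groups")
        rng = rng or np.random.default_rng()
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel_size, self.stride, self.dilation = kernel_size, stride, dilation
        self.groups = groups
        if padding == "same":
            padding = dilation * (kernel_size - 1) // 2
        self.padding = int(padding)
        fan_in = (in_channels // groups) * kernel_size * kernel_size
        self.weight = Tensor(_kaiming_uniform(
            rng, (out_channels, in_channels // groups, kernel_size, kernel_size),
            fan_in), requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, np.float32),
                           requires_grad=True) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding, dilation=self.dilation,
                      groups=self.groups)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, *, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.in_features, self.out_features = in_features, out_features
        self.weight = Tensor(_kaiming_uniform(rng, (in_features, out_features),
                                              in_features), requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, np.float32),
                           requires_grad=True) if bias else None

    def forward(self, x):
        y = x @ self.weight
        return y + self.bias if self.bias is not None else y


class BatchNorm2d(Module):
    def __init__(self, num_features: int, *, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.weight = Tensor(np.ones(num_features, np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(num_features, np.float32), requires_grad=True)
        self.register_buffer("running_mean", np.zeros(num_features, np.float32))
        self.register_buffer("running_var", np.ones(num_features, np.float32))

    def forward(self, x):
        return batch_norm2d(x, self.weight, self.bias, self.running_mean,
                            self.running_var, training=self.training,
                            momentum=self.momentum, eps=self.eps)


class GroupNorm2d(Module):
    """Group normalisation; batch-size independent alternative to BatchNorm."""

    def __init__(self, num_channels: int, num_groups: int = 8, *, eps: float = 1e-5):
        super().__init__()
        while num_channels % num_groups:
            num_groups -= 1
        self.num_groups, self.eps = num_groups, eps
        self.weight = Tensor(np.ones(num_channels, np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(num_channels, np.float32), requires_grad=True)

    def forward(self, x):
        B, C, H, W = x.shape
        g = self.num_groups
        xg = x.reshape(B, g, (C // g) * H * W)
        mu = xg.mean(axis=-1, keepdims=True)
        xc = xg - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xn = (xc * _rsqrt(var, self.eps)).reshape(B, C, H, W)
        return xn * self.weight.reshape(1, C, 1, 1) + self.bias.reshape(1, C, 1, 1)


def _rsqrt(t, eps):
    # 1/sqrt(t + eps), expressed through tape primitives
    return ((t + eps).log() * -0.5).exp()


class LayerNorm(Module):
    def __init__(self, dim: int, *, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.weight = Tensor(np.ones(dim, np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(dim, np.float32), requires_grad=True)

    def forward(self, x):
        return layer_norm(x, self.weight, self.bias, eps=self.eps)


class Upsample(Module):
    def __init__(self, scale: int = 2):
        super().__init__()
        self.scale = scale

    def forward(self, x):
        return upsample_bilinear(x, self.scale)
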