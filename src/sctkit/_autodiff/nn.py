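"""Layers, parameter containers and the Adam optimizer.

Weight initialization is driven by an explicit ``numpy.random.Generator`` so
that model construction is fully reproducible from a seed.
"""

from __future__ import annotations

import numpy as np

from . import ops
from .tensor import DTYPE, Tensor, leaky_relu


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class; children found by attribute walk (torch-style)."""

    def parameters(self) -> list[Parameter]:
        params = []
        for v in self.__dict__.values():
            params.extend(_collect(v))
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        named = dict(self.named_parameters())
        if set(named) != set(state):
            missing = set(named) ^ set(state)
            raise ValueError(f"state dict mismatch: {sorted(missing)}")
        for name, p in named.items():
            arr = np.asarray(state[name], dtype=DTYPE)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: "
                                 f"{arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def named_parameters(self, prefix: str = ""):
        for key, v in self.__dict__.items():
            yield from _named(v, f"{prefix}{key}")

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _collect(v):
    if isinstance(v, Parameter):
        return [v]
    if isinstance(v, Module):
        return v.parameters()
    if isinstance(v, (list, tuple)):
        out = []
        for item in v:
            out.extend(_collect(item))
        return out
    return []


def _named(v, name):
    if isinstance(v, Parameter):
        yield name, v
    elif isinstance(v, Module):
        yield from v.named_parameters(prefix=name + ".")
    elif isinstance(v, (list, tuple)):
        for i, item in enumerate(v):
            yield from _named(item, f"{name}.{i}")


class ModuleList(Module):
    def __init__(self, modules=()):
        self.items = list(modules)

    def __iter__(self):
        return iter(self.items)

    def __len__(self):
        return len(self.items)

    def __getitem__(self, i):
        return self.items[i]

    def append(self, m):
        self.items.append(m)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(DTYPE)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 stride: int = 1, padding: int | None = None,
                 bias: bool = True, zero_init: bool = False):
        if padding is None:
            padding = k // 2
        self.stride = stride
        self.padding = padding
        if zero_init:
            w = np.zeros((cout, cin, k, k), dtype=DTYPE)
        else:
            w = _he_init(rng, (cout, cin, k, k), cin * k * k)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(cout, dtype=DTYPE)) if bias else None

    def forward(self, x):
        return ops.conv2d(x, self.weight, self.bias,
                          stride=self.stride, padding=self.padding)


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, k: int, rng: np.random.Generator,
                 bias: bool = True):
        self.weight = Parameter(_he_init(rng, (channels, k, k), k * k))
        self.bias = Parameter(np.zeros(channels, dtype=DTYPE)) if bias else None

    def forward(self, x):
        return ops.depthwise_conv2d(x, self.weight, self.bias)


class ChannelLayerNorm(Module):
    """LayerNorm over the channel axis of (N, C, H, W), per spatial location."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones((1, channels, 1, 1), dtype=DTYPE))
        self.beta = Parameter(np.zeros((1, channels, 1, 1), dtype=DTYPE))
        self.eps = eps

    def forward(self, x):
        mu = x.mean(axis=1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=1, keepdims=True)
        xhat = xc * ((var + self.eps) ** -0.5)
        return xhat * self.gamma + self.beta


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x):
        return leaky_relu(x, self.slope)


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Adam:
    """Adam with per-parameter first/second moment state."""

    def __init__(self, params, lr: float = 1e-3,
                 beta1: float = 0.5, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
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
            v += (1 - b2) * (g * g)
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def state_dict(self) -> dict:
        return {"t": self.t, "m": [m.copy() for m in self.m],
                "v": [v.copy() for v in self.v], "lr": self.lr}

    def load_state_dict(self, state: dict):
        self.t = int(state["t"])
        self.lr = float(state["lr"])
        self.m = [np.asarray(m, dtype=DTYPE) for m in state["m"]]
        self.v = [np.asarray(v, dtype=DTYPE) for v in state["v"]]
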