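"""Neural-network building blocks on top of :mod:`tunet.autodiff`.

Modules hold :class:`Parameter` leaves and submodules; parameters are
discovered recursively by attribute registration, mirroring the familiar
torch-style API surface (``parameters()``, ``train()``, ``eval()``).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, layer_norm, softmax

__all__ = [
    "Parameter", "Module", "ModuleList", "Sequential",
    "Conv2d", "Linear", "BatchNorm2d", "LayerNorm",
    "MultiheadSelfAttention", "Mlp", "TransformerBlock", "SGD",
]

DTYPE = np.float32


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise KeyError(f"state dict mismatch: {sorted(missing)}")
        for k, p in own.items():
            p.data = np.asarray(state[k], dtype=p.dtype).reshape(p.shape).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._items = []
        for m in modules:
            self.append(m)

    def append(self, m: Module):
        setattr(self, str(len(self._items)), m)
        self._items.append(m)

    def __iter__(self):
        return iter(self._items)

    def __len__(self):
        return len(self._items)

    def __getitem__(self, i):
        return self._items[i]


class Sequential(ModuleList):
    def forward(self, x):
        for m in self._items:
            x = m(x)
        return x


class Conv2d(Module):
    """Same-padded stride-1 convolution with He-normal initialization."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 dilation: int = 1, bias: bool = True):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.standard_normal(
            (out_ch, in_ch, kernel, kernel), dtype=DTYPE) * std)
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self.dilation = dilation

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, dilation=self.dilation)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(2.0 / (in_dim + out_dim))  # Glorot
        self.weight = Parameter(rng.standard_normal((in_dim, out_dim), dtype=DTYPE) * std)
        self.bias = Parameter(np.zeros(out_dim))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)

    def forward(self, x: Tensor) -> Tensor:
        sh = (1, -1, 1, 1)
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
            xhat = xc / ((var + self.eps) ** 0.5)
        else:
            mu = Tensor(self.running_mean.reshape(sh))
            sd = Tensor(np.sqrt(self.running_var + self.eps).reshape(sh))
            xhat = (x - mu) / sd
        return xhat * self.gamma.reshape(sh) + self.beta.reshape(sh)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta, eps=self.eps)


class MultiheadSelfAttention(Module):
    """Standard multi-head scaled dot-product self-attention on (B, N, D)."""

    def __init__(self, dim: int, num_heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % num_heads:
            raise ValueError(f"embed_dim {dim} not divisible by num_heads {num_heads}")
        self.num_heads = num_heads
        self.head_dim = dim // num_heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        b, n, d = x.shape
        h, hd = self.num_heads, self.head_dim
        qkv = self.qkv(x).reshape(b, n, 3, h, hd).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]  # each (b, h, n, hd)
        attn = softmax((q @ k.transpose(0, 1, 3, 2)) * (hd ** -0.5), axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(b, n, d)
        return self.proj(out)


class Mlp(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class TransformerBlock(Module):
    """Pre-norm transformer unit: z' = MSA(LN(z)) + z; z = MLP(LN(z')) + z'."""

    def __init__(self, dim: int, num_heads: int, mlp_dim: int, rng: np.random.Generator):
        super().__init__()
        self.norm1 = LayerNorm(dim)
        self.attn = MultiheadSelfAttention(dim, num_heads, rng)
        self.norm2 = LayerNorm(dim)
        self.mlp = Mlp(dim, mlp_dim, rng)

    def forward(self, z: Tensor) -> Tensor:
        z = self.attn(self.norm1(z)) + z
        return self.mlp(self.norm2(z)) + z


class SGD:
    """Mini-batch SGD with momentum and decoupled-from-nothing L2 weight decay.

    Matches the classic formulation: v <- mu*v + (g + wd*p); p <- p - lr*v.
    """

    def __init__(self, params, lr: float, momentum: float = 0.0,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._vel = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
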