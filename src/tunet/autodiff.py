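"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine: a :class:`Tensor` wraps a numpy
array, records its parents and a backward closure, and :meth:`Tensor.backward`
runs the chain rule over a topological ordering.  Only the operations the
segmentation network needs are provided (elementwise arithmetic, matmul,
reductions, reshaping/indexing, 2-D convolution with dilation, pooling,
bilinear resampling and a few nonlinearities).  All operations preserve the
dtype of their inputs, so float64 can be used for finite-difference gradient
checks while float32 is the training default.
"""

from __future__ import annotations

import numpy as np
from scipy import special as _sp

__all__ = ["Tensor", "concatenate", "softmax", "layer_norm"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over the axes that numpy broadcasting introduced."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # axes of size 1 that were stretched
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        if self.data.dtype == np.float16:  # pragma: no cover - guard
            self.data = self.data.astype(np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def _wrap(x, ref: "Tensor") -> "Tensor":
        if isinstance(x, Tensor):
            return x
        return Tensor(np.asarray(x, dtype=ref.dtype))

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
        else:
            self.grad = self.grad + g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accum(np.asarray(grad, dtype=self.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = Tensor._wrap(other, self)
        out_data = self.data + other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(out_data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-Tensor._wrap(other, self))

    def __rsub__(self, other):
        return Tensor._wrap(other, self) + (-self)

    def __mul__(self, other):
        other = Tensor._wrap(other, self)
        out_data = self.data * other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._wrap(other, self)
        out_data = self.data / other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / (other.data ** 2), other.shape)
                )

        return Tensor._make(out_data, (self, other), bw)

    def __rtruediv__(self, other):
        return Tensor._wrap(other, self) / self

    def __pow__(self, p: float):
        out_data = self.data ** p

        def bw(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(out_data, (self,), bw)

    def __matmul__(self, other):
        other = Tensor._wrap(other, self)
        out_data = self.data @ other.data

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))

        return Tensor._make(out_data, (self, other), bw)

    # ------------------------------------------------------------- pointwise
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), bw)

    def log(self):
        out_data = np.log(self.data)

        def bw(g):
            self._accum(g / self.data)

        return Tensor._make(out_data, (self,), bw)

    def sqrt(self):
        return self ** 0.5

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient is zero outside [lo, hi] (standard clamp)."""
        out_data = np.clip(self.data, lo, hi)
        mask = (self.data >= lo) & (self.data <= hi)

        def bw(g):
            self._accum(g * mask)

        return Tensor._make(out_data, (self,), bw)

    def sigmoid(self):
        # numerically stable two-sided form
        x = self.data
        out_data = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                            np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
        out_data = out_data.astype(x.dtype, copy=False)

        def bw(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), bw)

    def gelu(self):
        """Exact (erf-based) Gaussian error linear unit."""
        x = self.data
        cdf = 0.5 * (1.0 + _sp.erf(x / np.sqrt(2.0)))
        out_data = (x * cdf).astype(x.dtype, copy=False)

        def bw(g):
            pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
            self._accum(g * (cdf + x * pdf))

        return Tensor._make(out_data, (self,), bw)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).astype(self.dtype))

        return Tensor._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ---------------------------------------------------------------- shaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        in_shape = self.shape

        def bw(g):
            self._accum(g.reshape(in_shape))

        return Tensor._make(out_data, (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(g):
            self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), bw)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor._make(out_data, (self,), bw)

    # ---------------------------------------------------------- spatial (NCHW)
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               dilation: int = 1):
        """Same-padded stride-1 2-D convolution (cross-correlation).

        ``self``: (N, C, H, W); ``weight``: (O, C, kh, kw); ``bias``: (O,).
        Padding keeps the spatial size for odd kernels at any dilation.
        """
        x, w = self.data, weight.data
        n, c, h, wd = x.shape
        o, c2, kh, kw = w.shape
        if c != c2:
            raise ValueError(f"conv2d channel mismatch: input {c}, weight {c2}")
        eh, ew = (kh - 1) * dilation + 1, (kw - 1) * dilation + 1
        ph, pw = eh // 2, ew // 2
        xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        view = np.lib.stride_tricks.sliding_window_view(xp, (eh, ew), axis=(2, 3))
        view = view[..., ::dilation, ::dilation]  # (n, c, h, w, kh, kw)
        cols = view.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * wd, c * kh * kw)
        wmat = w.reshape(o, c * kh * kw)
        out = cols @ wmat.T  # (n, h*w, o)
        if bias is not None:
            out = out + bias.data
        out_data = out.transpose(0, 2, 1).reshape(n, o, h, wd)

        def bw(g):
            gmat = g.reshape(n, o, h * wd).transpose(0, 2, 1)  # (n, h*w, o)
            if weight.requires_grad:
                gw = np.einsum("nlo,nlk->ok", gmat, cols, optimize=True)
                weight._accum(gw.reshape(o, c, kh, kw))
            if bias is not None and bias.requires_grad:
                bias._accum(gmat.sum(axis=(0, 1)))
            if self.requires_grad:
                gcols = gmat @ wmat  # (n, h*w, c*kh*kw)
                gcols = gcols.reshape(n, h, wd, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
                gxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        di, dj = i * dilation, j * dilation
                        gxp[:, :, di:di + h, dj:dj + wd] += gcols[:, :, :, :, i, j]
                self._accum(gxp[:, :, ph:ph + h, pw:pw + wd])

        parents = (self, weight) if bias is None else (self, weight, bias)
        return Tensor._make(out_data, parents, bw)

    def avg_pool2d(self, k: int):
        """Average pooling, kernel = stride = ``k``, ceil mode.

        Partial edge windows are averaged over valid pixels only.
        """
        x = self.data
        n, c, h, w = x.shape
        ho, wo = -(-h // k), -(-w // k)
        ph, pw = ho * k - h, wo * k - w
        xp = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)))
        ones = np.pad(np.ones((h, w), dtype=x.dtype), ((0, ph), (0, pw)))
        counts = ones.reshape(ho, k, wo, k).sum(axis=(1, 3))  # valid px per window
        sums = xp.reshape(n, c, ho, k, wo, k).sum(axis=(3, 5))
        out_data = sums / counts

        def bw(g):
            gw_ = (g / counts)[:, :, :, None, :, None]
            gxp = np.broadcast_to(gw_, (n, c, ho, k, wo, k)).reshape(
                n, c, ho * k, wo * k).copy()
            gxp *= np.pad(np.ones((h, w), dtype=x.dtype), ((0, ph), (0, pw)))
            self._accum(gxp[:, :, :h, :w])

        return Tensor._make(out_data, (self,), bw)

    def max_pool2d(self, k: int = 2):
        """Max pooling with kernel = stride = ``k``; H, W must divide by k."""
        x = self.data
        n, c, h, w = x.shape
        if h % k or w % k:
            raise ValueError(f"max_pool2d: spatial size {h}x{w} not divisible by {k}")
        ho, wo = h // k, w // k
        patches = x.reshape(n, c, ho, k, wo, k).transpose(0, 1, 2, 4, 3, 5)
        patches = patches.reshape(n, c, ho, wo, k * k)
        arg = patches.argmax(axis=-1)
        out_data = np.take_along_axis(patches, arg[..., None], axis=-1)[..., 0]

        def bw(g):
            gp = np.zeros((n, c, ho, wo, k * k), dtype=x.dtype)
            np.put_along_axis(gp, arg[..., None], g[..., None], axis=-1)
            gp = gp.reshape(n, c, ho, wo, k, k).transpose(0, 1, 2, 4, 3, 5)
            self._accum(gp.reshape(n, c, h, w))

        return Tensor._make(out_data, (self,), bw)

    def upsample_bilinear(self, out_hw: tuple):
        """Bilinear resize (align_corners=False) to ``out_hw`` = (H, W)."""
        x = self.data
        n, c, h, w = x.shape
        ho, wo = out_hw
        i0, i1, wi = _lin_idx(h, ho, x.dtype)
        j0, j1, wj = _lin_idx(w, wo, x.dtype)
        top = x[:, :, i0, :]
        bot = x[:, :, i1, :]
        rows = top * (1 - wi)[None, None, :, None] + bot * wi[None, None, :, None]
        left = rows[:, :, :, j0]
        right = rows[:, :, :, j1]
        out_data = left * (1 - wj) + right * wj

        def bw(g):
            grows = np.zeros((n, c, ho, w), dtype=x.dtype)
            np.add.at(grows.transpose(3, 0, 1, 2), j0, (g * (1 - wj)).transpose(3, 0, 1, 2))
            np.add.at(grows.transpose(3, 0, 1, 2), j1, (g * wj).transpose(3, 0, 1, 2))
            gx = np.zeros_like(x)
            gt = grows * (1 - wi)[None, None, :, None]
            gb = grows * wi[None, None, :, None]
            np.add.at(gx.transpose(2, 0, 1, 3), i0, gt.transpose(2, 0, 1, 3))
            np.add.at(gx.transpose(2, 0, 1, 3), i1, gb.transpose(2, 0, 1, 3))
            self._accum(gx)

        return Tensor._make(out_data, (self,), bw)


def _lin_idx(n_in: int, n_out: int, dtype):
    """Source indices and interpolation weights for 1-D bilinear resize."""
    dst = np.arange(n_out, dtype=np.float64)
    src = (dst + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0, n_in - 1)
    i0 = np.floor(src).astype(np.intp)
    i1 = np.minimum(i0 + 1, n_in - 1)
    w = (src - i0).astype(dtype)
    return i0, i1, w


def concatenate(tensors: list, axis: int) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))  # constant, no grad
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis."""
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    xhat = xc / ((var + eps) ** 0.5)
    return xhat * gamma + beta
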