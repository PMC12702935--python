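"""Reverse-mode automatic differentiation over NumPy arrays.

A minimal tape: every operation returns a new :class:`Tensor` holding its
forward value, references to its parents and a closure that propagates the
incoming cotangent to them.  ``Tensor.backward()`` runs the closures in
reverse topological order.  All arithmetic is float32; the engine is written
for clarity and BLAS-friendliness (im2col + matmul for convolutions), not
for generality beyond what the segmentation network needs.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "conv1d_channel",
    "conv2d",
    "batch_norm2d",
    "layer_norm",
    "upsample_bilinear",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """N-d array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(_parents)
        self._backward = _backward

    # -- introspection ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- autograd ---------------------------------------------------------
    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, self.requires_grad or other.requires_grad,
                     (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, self.requires_grad or other.requires_grad,
                     (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, self.requires_grad or other.requires_grad,
                     (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g * self.data / other.data ** 2,
                                               other.data.shape))

        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, self.requires_grad or other.requires_grad,
                     (self, other))

        def bwd(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.data.shape))

        out._backward = bwd
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        out._backward = bwd
        return out

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(np.ascontiguousarray(self.data.transpose(axes)),
                     self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g.transpose(tuple(inv)))
        return out

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).astype(np.float32))

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def amax(self, axis=None, keepdims=False):
        m = self.data.max(axis=axis, keepdims=True)
        out_data = m if keepdims or axis is None else np.squeeze(m, axis=axis)
        if axis is None and not keepdims:
            out_data = out_data.reshape(())
        out = Tensor(out_data, self.requires_grad, (self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            mask = (self.data == m)
            count = mask.sum(axis=axis, keepdims=True) if axis is not None else mask.sum()
            self._accumulate((mask * g / count).astype(np.float32))

        out._backward = bwd
        return out

    # -- nonlinearities ---------------------------------------------------
    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g * (self.data > 0))
        return out

    def sigmoid(self):
        # stable two-branch form: never exponentiates a large positive value
        x = self.data
        y = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                     np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
        out = Tensor(y, self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g * y * (1.0 - y))
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * y)
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g / self.data)
        return out

    def softmax(self, axis=-1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(y, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                dot = (g * y).sum(axis=axis, keepdims=True)
                self._accumulate((y * (g - dot)).astype(np.float32))

        out._backward = bwd
        return out

    def log_softmax(self, axis=-1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        ls = z - lse
        out = Tensor(ls, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                p = np.exp(ls)
                self._accumulate((g - p * g.sum(axis=axis, keepdims=True)).astype(np.float32))

        out._backward = bwd
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    out._backward = bwd
    return out


# -- convolution ----------------------------------------------------------

def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int, dilation: int):
    """(B, C, Hp, Wp) -> (B, Ho*Wo, C*kh*kw) patch matrix."""
    kh_eff = (kh - 1) * dilation + 1
    kw_eff = (kw - 1) * dilation + 1
    B, C, Hp, Wp = xp.shape
    Ho = (Hp - kh_eff) // stride + 1
    Wo = (Wp - kw_eff) // stride + 1
    v = np.lib.stride_tricks.sliding_window_view(xp, (kh_eff, kw_eff), axis=(2, 3))
    v = v[:, :, ::stride, ::stride, ::dilation, ::dilation]
    col = np.ascontiguousarray(v.transpose(0, 2, 3, 1, 4, 5))
    return col.reshape(B, Ho * Wo, C * kh * kw), Ho, Wo


def _col2im(gcol: np.ndarray, x_shape, kh, kw, stride, dilation, padding, Ho, Wo):
    B, C, H, W = x_shape
    Hp, Wp = H + 2 * padding, W + 2 * padding
    gxp = np.zeros((B, C, Hp, Wp), dtype=np.float32)
    g6 = gcol.reshape(B, Ho, Wo, C, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    for i in range(kh):
        for j in range(kw):
            gxp[:, :,
                i * dilation: i * dilation + stride * Ho: stride,
                j * dilation: j * dilation + stride * Wo: stride] += g6[:, :, :, :, i, j]
    if padding:
        gxp = gxp[:, :, padding:-padding, padding:-padding]
    return gxp


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, *, stride: int = 1,
           padding: int = 0, dilation: int = 1, groups: int = 1) -> Tensor:
    """2-d cross-correlation. ``w`` has shape (O, C/groups, kh, kw)."""
    B, C, H, W = x.data.shape
    O, Cg, kh, kw = w.data.shape
    if C % groups or O % groups or Cg != C // groups:
        raise ValueError(
            f"conv2d: channels {C}->{O} incompatible with groups={groups}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
        if padding else x.data
    col, Ho, Wo = _im2col(xp, kh, kw, stride, dilation)
    K = Cg * kh * kw
    if groups == 1:
        wmat = w.data.reshape(O, K)
        out = col @ wmat.T                      # (B, HoWo, O)
        out_data = out.transpose(0, 2, 1).reshape(B, O, Ho, Wo)
    else:
        Og = O // groups
        colg = col.reshape(B, Ho * Wo, groups, K).transpose(2, 0, 1, 3)
        wmat = w.data.reshape(groups, Og, K)
        outg = colg @ wmat.transpose(0, 2, 1)[:, None]   # (g, B, HoWo, Og)
        out_data = np.ascontiguousarray(outg.transpose(1, 0, 3, 2)).reshape(
            B, O, Ho, Wo)
    if b is not None:
        out_data = out_data + b.data.reshape(1, O, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, any(p.requires_grad for p in parents), parents)

    def bwd(g):
        gmat = g.reshape(B, O, Ho * Wo)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if groups == 1:
            gflat = gmat.transpose(0, 2, 1)            # (B, HoWo, O)
            if w.requires_grad:
                gw = np.tensordot(gflat, col, axes=([0, 1], [0, 1]))  # (O, K)
                w._accumulate(gw.reshape(w.data.shape))
            if x.requires_grad:
                gcol = gflat @ w.data.reshape(O, K)    # (B, HoWo, K)
                x._accumulate(_col2im(gcol, x.data.shape, kh, kw, stride,
                                      dilation, padding, Ho, Wo))
        else:
            Og = O // groups
            gg = gmat.reshape(B, groups, Og, Ho * Wo).transpose(1, 0, 3, 2)  # (g,B,HoWo,Og)
            colg = col.reshape(B, Ho * Wo, groups, K).transpose(2, 0, 1, 3)
            if w.requires_grad:
                gw = np.einsum("gbno,gbnk->gok", gg, colg, optimize=True)
                w._accumulate(gw.reshape(w.data.shape))
            if x.requires_grad:
                gcolg = gg @ w.data.reshape(groups, Og, K)[:, None]  # (g,B,HoWo,K)
                gcol = gcolg.transpose(1, 2, 0, 3).reshape(B, Ho * Wo, groups * K)
                x._accumulate(_col2im(gcol, x.data.shape, kh, kw, stride,
                                      dilation, padding, Ho, Wo))

    out._backward = bwd
    return out


def conv1d_channel(x: Tensor, w: Tensor) -> Tensor:
    """1-d "same" convolution along the channel axis of a (B, C) descriptor.

    ``w`` has shape (k,) with k odd; zero padding of (k-1)/2, no bias — the
    weight-sharing cross-channel interaction used by ECA.
    """
    k = w.data.shape[0]
    if k % 2 == 0:
        raise ValueError("conv1d_channel: kernel size must be odd")
    pad = (k - 1) // 2
    B, C = x.data.shape
    xp = np.pad(x.data, ((0, 0), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)  # (B, C, k)
    out = Tensor(win @ w.data, x.requires_grad or w.requires_grad, (x, w))

    def bwd(g):
        if w.requires_grad:
            w._accumulate(np.tensordot(g, win, axes=([0, 1], [0, 1])))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for j in range(k):
                gxp[:, j:j + C] += g * w.data[j]
            x._accumulate(gxp[:, pad:pad + C] if pad else gxp)

    out._backward = bwd
    return out


# -- normalisation --------------------------------------------------------

def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor, running_mean, running_var,
                 *, training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Fused batch normalisation over (B, H, W) per channel.

    ``running_mean``/``running_var`` are plain ndarrays updated in place when
    ``training`` is true.
    """
    B, C, H, W = x.data.shape
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= (1.0 - momentum)
        running_mean += momentum * mean
        running_var *= (1.0 - momentum)
        n = B * H * W
        running_var += momentum * var * (n / max(n - 1, 1))
    else:
        mean, var = running_mean, running_var
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(1, C, 1, 1)) * invstd.reshape(1, C, 1, 1)
    out_data = gamma.data.reshape(1, C, 1, 1) * xhat + beta.data.reshape(1, C, 1, 1)
    out = Tensor(out_data, x.requires_grad or gamma.requires_grad or beta.requires_grad,
                 (x, gamma, beta))

    def bwd(g):
        gsum = g.sum(axis=(0, 2, 3))
        gx_hat_sum = (g * xhat).sum(axis=(0, 2, 3))
        if beta.requires_grad:
            beta._accumulate(gsum)
        if gamma.requires_grad:
            gamma._accumulate(gx_hat_sum)
        if x.requires_grad:
            scale = (gamma.data * invstd).reshape(1, C, 1, 1)
            if training:
                n = B * H * W
                gx = scale * (g - gsum.reshape(1, C, 1, 1) / n
                              - xhat * gx_hat_sum.reshape(1, C, 1, 1) / n)
            else:
                gx = scale * g
            x._accumulate(gx.astype(np.float32))

    out._backward = bwd
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, *, eps: float = 1e-5) -> Tensor:
    """Layer normalisation over the last axis."""
    mean = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean) * invstd
    out = Tensor(gamma.data * xhat + beta.data,
                 x.requires_grad or gamma.requires_grad or beta.requires_grad,
                 (x, gamma, beta))

    def bwd(g):
        red = tuple(range(g.ndim - 1))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=red))
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=red))
        if x.requires_grad:
            n = x.data.shape[-1]
            gh = g * gamma.data
            gx = invstd * (gh - gh.mean(axis=-1, keepdims=True)
                           - xhat * (gh * xhat).mean(axis=-1, keepdims=True))
            x._accumulate(gx.astype(np.float32))

    out._backward = bwd
    return out


# -- resampling -----------------------------------------------------------

def _linear_weights(n_in: int, n_out: int):
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    i0 = np.clip(np.floor(src).astype(np.int64), 0, n_in - 1)
    i1 = np.clip(i0 + 1, 0, n_in - 1)
    w1 = np.clip(src - i0, 0.0, 1.0).astype(np.float32)
    return i0, i1, w1


def upsample_bilinear(x: Tensor, scale: int = 2) -> Tensor:
    """Bilinear up-sampling by an integer factor (half-pixel convention)."""
    B, C, H, W = x.data.shape
    Ho, Wo = H * scale, W * scale
    y0, y1, wy = _linear_weights(H, Ho)
    x0, x1, wx = _linear_weights(W, Wo)
    rows = x.data[:, :, y0, :] * (1 - wy)[None, None, :, None] \
        + x.data[:, :, y1, :] * wy[None, None, :, None]
    out_data = rows[:, :, :, x0] * (1 - wx) + rows[:, :, :, x1] * wx
    out = Tensor(out_data, x.requires_grad, (x,))

    def bwd(g):
        if not x.requires_grad:
            return
        grows = np.zeros((B, C, Ho, W), dtype=np.float32)
        np.add.at(grows, (slice(None), slice(None), slice(None), x0), g * (1 - wx))
        np.add.at(grows, (slice(None), slice(None), slice(None), x1), g * wx)
        gx = np.zeros((B, C, H, W), dtype=np.float32)
        np.add.at(gx, (slice(None), slice(None), y0),
                  grows * (1 - wy)[None, None, :, None])
        np.add.at(gx, (slice(None), slice(None), y1),
                  grows * wy[None, None, :, None])
        x._accumulate(gx)

    out._backward = bwd
    return out
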