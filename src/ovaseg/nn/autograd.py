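"""A compact reverse-mode automatic differentiation engine on NumPy arrays.

Tensors wrap float32 ndarrays and record the operations that produced them;
``Tensor.backward()`` runs the reverse sweep over the recorded graph.  The op
set is exactly what small 2D convolutional networks need: broadcasting
arithmetic, matmul, conv2d (im2col), 2x2 max pooling, nearest-neighbour
upsampling, batch normalisation, channel concatenation, relu/sigmoid,
reductions, and a numerically stable sigmoid cross-entropy.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                node._parents = ()
                node._backward = None

    def _accum(self, g: np.ndarray) -> None:
        g = g.astype(np.float32, copy=False)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    # -- basic arithmetic --------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def __add__(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._from_op(self.data + other.data, (self, other), backward)

    def __sub__(self, other: "Tensor") -> "Tensor":
        return self + (other * -1.0)

    def __mul__(self, other) -> "Tensor":
        if np.isscalar(other):
            s = float(other)

            def backward_s(g):
                if self.requires_grad:
                    self._accum(g * s)

            return Tensor._from_op(self.data * s, (self,), backward_s)
        other = _as_tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._from_op(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        if np.isscalar(other):
            return self * (1.0 / float(other))
        other = _as_tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
                )

        return Tensor._from_op(self.data / other.data, (self, other), backward)

    def pow(self, exponent: float) -> "Tensor":
        e = float(exponent)
        out_data = self.data**e

        def backward(g):
            if self.requires_grad:
                base = self.data
                if e < 1.0:  # avoid inf gradient exactly at 0 for fractional powers
                    base = np.maximum(base, 1e-12)
                self._accum(g * e * base ** (e - 1.0))

        return Tensor._from_op(out_data, (self,), backward)

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape))

        return Tensor._from_op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape) -> "Tensor":
        orig = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return Tensor._from_op(self.data.reshape(*shape), (self,), backward)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return Tensor._from_op(self.data @ other.data, (self, other), backward)

    # -- nonlinearities ----------------------------------------------------

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._from_op(self.data * mask, (self,), backward)

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60.0, 60.0)))

        def backward(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        return Tensor._from_op(s, (self,), backward)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# ---------------------------------------------------------------------------
# structured ops
# ---------------------------------------------------------------------------

def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._from_op(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, padding: int = 1) -> Tensor:
    """2D convolution, NCHW in/out, square kernel, symmetric zero padding.

    Internally uses im2col in NHWC layout so both the forward GEMM and the
    col2im scatter in the backward pass run on contiguous arrays.
    """
    n, c, h, wd = x.data.shape
    f, c2, kh, kw = w.data.shape
    assert c == c2, "channel mismatch"
    ho = (h + 2 * padding - kh) // stride + 1
    wo = (wd + 2 * padding - kw) // stride + 1
    xp = np.ascontiguousarray(
        np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))).transpose(
            0, 2, 3, 1
        )
    )  # (N, Hp, Wp, C)
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
    # (N, Ho', Wo', C, kh, kw) view; reshape materialises the im2col matrix
    cols = win[:, ::stride, ::stride].reshape(n, ho, wo, c * kh * kw)
    # weight matrix in the same (C, kh, kw) trailing order as the windows
    w2 = w.data.transpose(1, 2, 3, 0).reshape(c * kh * kw, f)
    out = cols @ w2  # (N, Ho, Wo, F)
    if b is not None:
        out += b.data
    out_nchw = np.ascontiguousarray(out.transpose(0, 3, 1, 2))

    def backward(g):
        gout = np.ascontiguousarray(g.transpose(0, 2, 3, 1))  # (N, Ho, Wo, F)
        if b is not None and b.requires_grad:
            b._accum(gout.reshape(-1, f).sum(axis=0))
        if w.requires_grad:
            gw = np.tensordot(cols, gout, axes=([0, 1, 2], [0, 1, 2]))  # (C*kh*kw, F)
            w._accum(gw.reshape(c, kh, kw, f).transpose(3, 0, 1, 2))
        if x.requires_grad:
            gcols = (gout @ w2.T).reshape(n, ho, wo, c, kh, kw)
            gxp = np.zeros_like(xp)
            for ki in range(kh):
                for kj in range(kw):
                    gxp[:, ki : ki + stride * ho : stride, kj : kj + stride * wo : stride, :] += gcols[
                        :, :, :, :, ki, kj
                    ]
            gx = gxp.transpose(0, 3, 1, 2)
            if padding:
                gx = gx[:, :, padding:-padding, padding:-padding]
            x._accum(np.ascontiguousarray(gx))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._from_op(out_nchw, parents, backward)


def maxpool2d(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2 (even spatial sizes only)."""
    n, c, h, w = x.data.shape
    assert h % 2 == 0 and w % 2 == 0, "maxpool2d needs even spatial dims"
    quads = (
        x.data[:, :, 0::2, 0::2],
        x.data[:, :, 0::2, 1::2],
        x.data[:, :, 1::2, 0::2],
        x.data[:, :, 1::2, 1::2],
    )
    out = np.maximum(np.maximum(quads[0], quads[1]), np.maximum(quads[2], quads[3]))

    def backward(g):
        if not x.requires_grad:
            return
        gx = np.zeros_like(x.data)
        taken = np.zeros(out.shape, dtype=bool)
        views = (
            gx[:, :, 0::2, 0::2],
            gx[:, :, 0::2, 1::2],
            gx[:, :, 1::2, 0::2],
            gx[:, :, 1::2, 1::2],
        )
        for q, view in zip(quads, views):
            hit = (q == out) & ~taken  # first-window-position tie-break
            view += g * hit
            taken |= hit
        x._accum(gx)

    return Tensor._from_op(out, (x,), backward)


def upsample_nearest2x(x: Tensor) -> Tensor:
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        if not x.requires_grad:
            return
        n, c, h, w = x.data.shape
        gx = g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))
        x._accum(gx)

    return Tensor._from_op(out, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C)."""
    n, c, h, w = x.data.shape
    out = x.data.mean(axis=(2, 3))

    def backward(g):
        if x.requires_grad:
            x._accum(np.broadcast_to(g[:, :, None, None], x.data.shape) / (h * w))

    return Tensor._from_op(out, (x,), backward)


def batch_norm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalisation over (N, H, W); updates running stats in place."""
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv = (1.0 / np.sqrt(var + eps)).astype(np.float32)
    mu32 = np.asarray(mu, dtype=np.float32)
    xhat = (x.data - mu32[None, :, None, None]) * inv[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3)))
        if not x.requires_grad:
            return
        gscaled = g * gamma.data[None, :, None, None]
        if training:
            m = g.shape[0] * g.shape[2] * g.shape[3]
            sum_g = gscaled.sum(axis=(0, 2, 3))
            sum_gx = (gscaled * xhat).sum(axis=(0, 2, 3))
            gx = (
                gscaled
                - (sum_g / m)[None, :, None, None]
                - xhat * (sum_gx / m)[None, :, None, None]
            ) * inv[None, :, None, None]
        else:
            gx = gscaled * inv[None, :, None, None]
        x._accum(gx)

    return Tensor._from_op(out, (x, gamma, beta), backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= p).astype(np.float32) / (1.0 - p)

    def backward(g):
        if x.requires_grad:
            x._accum(g * mask)

    return Tensor._from_op(x.data * mask, (x,), backward)


def sigmoid_ce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean of the numerically stable binary cross-entropy on logits.

    Uses max(z,0) - z*y + log(1 + exp(-|z|)), which stays finite for |z| up
    to at least 1e4; gradient is (sigma(z) - y) / n.
    """
    z = logits.data
    y = np.asarray(targets, dtype=np.float32)
    loss = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    out = loss.mean()

    def backward(g):
        if logits.requires_grad:
            s = 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))
            logits._accum(g * (s - y) / y.size)

    return Tensor._from_op(out, (logits,), backward)
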