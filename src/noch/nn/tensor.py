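"""A minimal reverse-mode automatic-differentiation engine on NumPy arrays.

Implements exactly the operations the translation network needs: broadcasted
arithmetic, matmul, reductions, stable log-sum-exp, 2-D convolution (im2col),
reflection/zero padding, nearest-neighbour upsampling and index gathering.
All data is float64; gradients are accumulated into ``Tensor.grad`` by
``Tensor.backward()`` over a topologically sorted graph.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

#: dtype for newly created tensors; float64 by default for exact oracle
#: tests, switchable to float32 for training throughput.
DTYPE = np.float64


@contextmanager
def default_dtype(dtype):
    global DTYPE
    old, DTYPE = DTYPE, np.dtype(dtype)
    try:
        yield
    finally:
        DTYPE = old

__all__ = [
    "Tensor", "as_tensor", "concat", "logsumexp", "conv2d", "pad2d",
    "upsample_nearest2x", "index_take", "relu", "leaky_relu", "tanh",
    "exp", "log", "softplus", "logsigmoid", "sigmoid",
    "instance_norm", "default_dtype",
]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    # -- construction -----------------------------------------------------
    @staticmethod
    def _op(data, parents, backward):
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

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

    def item(self) -> float:
        return float(self.data)

    def __float__(self):
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- autograd ---------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        for node in topo:
            node.grad = None
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, grad):
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        a, b = self, as_tensor(other)

        def bwd(g):
            a._accum(_unbroadcast(g, a.shape))
            b._accum(_unbroadcast(g, b.shape))

        return Tensor._op(a.data + b.data, (a, b), bwd)

    __radd__ = __add__

    def __mul__(self, other):
        a, b = self, as_tensor(other)

        def bwd(g):
            a._accum(_unbroadcast(g * b.data, a.shape))
            b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor._op(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        return self * as_tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        a, n = self, float(exponent)

        def bwd(g):
            a._accum(g * n * a.data ** (n - 1.0))

        return Tensor._op(a.data ** n, (a,), bwd)

    def __matmul__(self, other):
        a, b = self, as_tensor(other)
        out_data = a.data @ b.data

        def bwd(g):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            a._accum(_unbroadcast(ga, a.shape))
            b._accum(_unbroadcast(gb, b.shape))

        return Tensor._op(out_data, (a, b), bwd)

    # -- reductions / shape ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def bwd(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accum(np.broadcast_to(gg, a.shape).copy())

        return Tensor._op(a.data.sum(axis=axis, keepdims=keepdims), (a,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[ax] for ax in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bwd(g):
            a._accum(g.reshape(a.shape))

        return Tensor._op(a.data.reshape(shape), (a,), bwd)

    def transpose(self, *axes):
        a = self
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bwd(g):
            a._accum(g.transpose(inv))

        return Tensor._op(a.data.transpose(axes), (a,), bwd)

    @property
    def T(self):
        return self.transpose(*reversed(range(self.ndim)))


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# -- pointwise nonlinearities ---------------------------------------------

def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0

    def bwd(g):
        x._accum(g * mask)

    return Tensor._op(np.where(mask, x.data, 0.0), (x,), bwd)


def leaky_relu(x: Tensor, alpha: float = 0.2) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0

    def bwd(g):
        x._accum(g * np.where(mask, 1.0, alpha))

    return Tensor._op(np.where(mask, x.data, alpha * x.data), (x,), bwd)


def tanh(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out_data = np.tanh(x.data)

    def bwd(g):
        x._accum(g * (1.0 - out_data ** 2))

    return Tensor._op(out_data, (x,), bwd)


def exp(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out_data = np.exp(x.data)

    def bwd(g):
        x._accum(g * out_data)

    return Tensor._op(out_data, (x,), bwd)


def log(x: Tensor) -> Tensor:
    x = as_tensor(x)

    def bwd(g):
        x._accum(g / x.data)

    return Tensor._op(np.log(x.data), (x,), bwd)


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out_data = 0.5 * (1.0 + np.tanh(0.5 * x.data))  # stable logistic

    def bwd(g):
        x._accum(g * out_data * (1.0 - out_data))

    return Tensor._op(out_data, (x,), bwd)


def softplus(x: Tensor) -> Tensor:
    """log(1 + exp(x)), computed without overflow."""
    x = as_tensor(x)
    out_data = np.maximum(x.data, 0.0) + np.log1p(np.exp(-np.abs(x.data)))
    sig = 0.5 * (1.0 + np.tanh(0.5 * x.data))

    def bwd(g):
        x._accum(g * sig)

    return Tensor._op(out_data, (x,), bwd)


def logsigmoid(x: Tensor) -> Tensor:
    return -softplus(-as_tensor(x))


def logsumexp(x: Tensor, axis: int = -1, keepdims: bool = False) -> Tensor:
    """Numerically stable log-sum-exp with a softmax backward pass."""
    x = as_tensor(x)
    m = np.max(x.data, axis=axis, keepdims=True)
    e = np.exp(x.data - m)
    s = e.sum(axis=axis, keepdims=True)
    out_data = m + np.log(s)
    soft = e / s
    if not keepdims:
        out_data = np.squeeze(out_data, axis=axis)

    def bwd(g):
        gg = g if keepdims else np.expand_dims(g, axis)
        x._accum(gg * soft)

    return Tensor._op(out_data, (x,), bwd)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, gpart in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(gpart)

    return Tensor._op(np.concatenate([t.data for t in tensors], axis=axis),
                      tuple(tensors), bwd)


def index_take(x: Tensor, indices, axis: int = 0) -> Tensor:
    """Gather rows/slices along ``axis``; backward scatter-adds."""
    x = as_tensor(x)
    idx = np.asarray(indices, dtype=np.intp)

    def bwd(g):
        gx = np.zeros_like(x.data)
        np.add.at(gx, (slice(None),) * axis + (idx,), g)
        x._accum(gx)

    return Tensor._op(np.take(x.data, idx, axis=axis), (x,), bwd)


# -- spatial ops ------------------------------------------------------------

def pad2d(x: Tensor, pad: tuple, mode: str = "zeros") -> Tensor:
    """Pad the last two axes of a (N, C, H, W) tensor.

    pad = (top, bottom, left, right). Modes: "zeros", "reflect".
    """
    x = as_tensor(x)
    pt, pb, pl, pr = pad
    spec = [(0, 0)] * (x.ndim - 2) + [(pt, pb), (pl, pr)]
    if mode == "zeros":
        out_data = np.pad(x.data, spec)

        def bwd(g):
            sl = (Ellipsis, slice(pt, g.shape[-2] - pb), slice(pl, g.shape[-1] - pr))
            x._accum(g[sl])

    elif mode == "reflect":
        out_data = np.pad(x.data, spec, mode="reflect")

        def fold(g, pb_, pa_, axis):
            """Collapse reflect padding along one axis by slice additions."""
            n = g.shape[axis] - pb_ - pa_
            sl = lambda s: (Ellipsis, s) if axis == -1 else (Ellipsis, s, slice(None))
            core = g[sl(slice(pb_, pb_ + n))].copy()
            if pb_:
                core[sl(slice(1, pb_ + 1))] += g[sl(slice(pb_ - 1, None, -1))]
            if pa_:
                core[sl(slice(n - 1 - pa_, n - 1))] += \
                    g[sl(slice(None, pb_ + n - 1, -1))]
            return core

        def bwd(g):
            x._accum(fold(fold(g, pt, pb, -2), pl, pr, -1))

    else:
        raise ValueError(f"unknown pad mode: {mode!r}")
    return Tensor._op(out_data, (x,), bwd)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int | tuple = 1) -> Tensor:
    """Valid (unpadded) 2-D convolution of (N,C,H,W) with (O,C,kh,kw)."""
    x, w = as_tensor(x), as_tensor(w)
    sh, sw = (stride, stride) if isinstance(stride, int) else stride
    N, C, H, W = x.shape
    O, Cw, kh, kw = w.shape
    if Cw != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight {Cw}")
    if kh > H or kw > W:
        raise ValueError("kernel larger than input")
    win = sliding_window_view(x.data, (kh, kw), axis=(2, 3))[:, :, ::sh, ::sw]
    Ho, Wo = win.shape[2], win.shape[3]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        N, Ho * Wo, C * kh * kw)
    wmat = w.data.reshape(O, -1)
    out_data = (cols @ wmat.T).transpose(0, 2, 1).reshape(N, O, Ho, Wo)
    if b is not None:
        b = as_tensor(b)
        out_data = out_data + b.data.reshape(1, O, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        gmat = np.ascontiguousarray(
            g.reshape(N, O, Ho * Wo).transpose(0, 2, 1))  # (N, HoWo, O)
        if w.requires_grad:
            gw = gmat.reshape(-1, O).T @ cols.reshape(-1, C * kh * kw)
            w._accum(gw.reshape(w.shape))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            if sh == sw == 1:
                # transposed convolution as one GEMM: correlate the padded
                # output gradient with the flipped kernel
                gp = np.pad(g, ((0, 0), (0, 0), (kh - 1, kh - 1),
                                (kw - 1, kw - 1)))
                gwin = sliding_window_view(gp, (kh, kw), axis=(2, 3))
                gcols = np.ascontiguousarray(
                    gwin.transpose(0, 2, 3, 1, 4, 5)).reshape(N, H * W, -1)
                wf = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(C, -1)
                gx = (gcols @ wf.T).transpose(0, 2, 1).reshape(N, C, H, W)
            else:
                gcols = (gmat @ wmat).reshape(N, Ho, Wo, C, kh, kw)
                gx = np.zeros(x.shape, dtype=g.dtype)
                for i in range(kh):
                    for j in range(kw):
                        gx[:, :, i:i + sh * Ho:sh, j:j + sw * Wo:sw] += \
                            gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            x._accum(gx)

    return Tensor._op(out_data, parents, bwd)


def instance_norm(x: Tensor, gamma: Tensor | None = None,
                  beta: Tensor | None = None, eps: float = 1e-5) -> Tensor:
    """Fused per-sample, per-channel normalisation over the spatial axes of a
    (N, C, H, W) tensor, with optional (1, C, 1, 1) affine parameters."""
    x = as_tensor(x)
    mu = x.data.mean(axis=(2, 3), keepdims=True)
    var = x.data.var(axis=(2, 3), keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv_std
    if gamma is not None:
        out_data = xhat * gamma.data + beta.data
        parents = (x, gamma, beta)
    else:
        out_data = xhat
        parents = (x,)

    def bwd(g):
        if gamma is not None:
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=(0, 2, 3), keepdims=True))
            if beta.requires_grad:
                beta._accum(g.sum(axis=(0, 2, 3), keepdims=True))
            gh = g * gamma.data
        else:
            gh = g
        if x.requires_grad:
            m1 = gh.mean(axis=(2, 3), keepdims=True)
            m2 = (gh * xhat).mean(axis=(2, 3), keepdims=True)
            x._accum(inv_std * (gh - m1 - xhat * m2))

    return Tensor._op(out_data, parents, bwd)


def upsample_nearest2x(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out_data = x.data.repeat(2, axis=-2).repeat(2, axis=-1)

    def bwd(g):
        N, C, H2, W2 = g.shape
        x._accum(g.reshape(N, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5)))

    return Tensor._op(out_data, (x,), bwd)
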