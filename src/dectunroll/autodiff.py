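"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery to express and train the unrolled network: elementwise
arithmetic, reductions, N-dimensional convolution, pooling/upsampling, and a
hook for operations with hand-written backward rules (the data-consistency
layer).  Tensors are channels-first without a batch axis; one sample flows
through the graph at a time and batching is emulated by gradient
accumulation, which is exact here because no layer couples samples.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concat", "relu", "sigmoid", "convnd", "avg_pool",
           "upsample_nearest", "pad_spatial", "crop_spatial", "group_norm",
           "custom_op"]


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(),
                 backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- graph traversal ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient needs a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=float)
        for t in reversed(topo):
            if t._backward is None:
                continue
            grads = t._backward(t.grad)
            for p, g in zip(t._parents, grads):
                if g is None or not p.requires_grad:
                    continue
                g = _unbroadcast(g, p.data.shape)
                p.grad = g if p.grad is None else p.grad + g

    def zero_grad(self):
        self.grad = None

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = _wrap(other)
        return Tensor(self.data + other.data, parents=(self, other),
                      backward=lambda g: (g, g))

    __radd__ = __add__

    def __mul__(self, other):
        other = _wrap(other)
        return Tensor(self.data * other.data, parents=(self, other),
                      backward=lambda g: (g * other.data, g * self.data))

    __rmul__ = __mul__

    def __neg__(self):
        return Tensor(-self.data, parents=(self,), backward=lambda g: (-g,))

    def __sub__(self, other):
        return self + (-_wrap(other))

    def __rsub__(self, other):
        return _wrap(other) + (-self)

    def __truediv__(self, other):
        return self * _wrap(other) ** -1.0

    def __rtruediv__(self, other):
        return _wrap(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out = self.data ** exponent
        return Tensor(out, parents=(self,),
                      backward=lambda g: (g * exponent * self.data ** (exponent - 1.0),))

    # -- reductions / shape ---------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            return (np.broadcast_to(gg, self.data.shape).copy(),)

        return Tensor(out, parents=(self,), backward=bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        shape = shape[0] if len(shape) == 1 and isinstance(shape[0], tuple) else shape
        old = self.data.shape
        return Tensor(self.data.reshape(shape), parents=(self,),
                      backward=lambda g: (g.reshape(old),))

    def __getitem__(self, idx):
        def bw(g):
            gg = np.zeros_like(self.data)
            gg[idx] = g
            return (gg,)

        return Tensor(self.data[idx], parents=(self,), backward=bw)

    def exp(self):
        out = np.exp(self.data)
        return Tensor(out, parents=(self,), backward=lambda g: (g * out,))

    def item(self):
        return float(self.data)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad, shape):
    """Reduce a broadcast gradient back to the parent's shape."""
    g = np.asarray(grad)
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, (gs, ps) in enumerate(zip(g.shape, shape)):
        if ps == 1 and gs != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


# -- nonlinearities -----------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor(np.where(mask, x.data, 0.0), parents=(x,),
                  backward=lambda g: (g * mask,))


def sigmoid(x: Tensor) -> Tensor:
    out = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))
    return Tensor(out, parents=(x,), backward=lambda g: (g * out * (1 - out),))


# -- structural ops -----------------------------------------------------------

def concat(tensors, axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors),
                  backward=bw)


def pad_spatial(x: Tensor, pads) -> Tensor:
    """Zero-pad spatial axes (all but the leading channel axis)."""
    width = [(0, 0)] + list(pads)
    sl = tuple([slice(None)] + [slice(p0, None if p1 == 0 else -p1)
                                for p0, p1 in pads])

    def bw(g):
        return (g[sl],)

    return Tensor(np.pad(x.data, width), parents=(x,), backward=bw)


def crop_spatial(x: Tensor, pads) -> Tensor:
    """Inverse of :func:`pad_spatial` for the same pad widths."""
    sl = tuple([slice(None)] + [slice(p0, None if p1 == 0 else -p1)
                                for p0, p1 in pads])
    width = [(0, 0)] + list(pads)

    def bw(g):
        return (np.pad(g, width),)

    return Tensor(x.data[sl], parents=(x,), backward=bw)


def convnd(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padding stride-1 correlation.

    ``x``: (C_in, *spatial); ``w``: (C_out, C_in, *kernel); odd kernels only.
    """
    nd = x.ndim - 1
    ker = w.shape[2:]
    pads = [(k // 2, k // 2) for k in ker]
    xp = np.pad(x.data, [(0, 0)] + pads)
    patches = sliding_window_view(xp, ker, axis=tuple(range(1, nd + 1)))
    # patches: (C_in, *spatial, *kernel)
    axes_p = [0] + list(range(nd + 1, nd + 1 + nd))
    axes_w = [1] + list(range(2, 2 + nd))
    out = np.tensordot(w.data, patches, axes=(axes_w, axes_p))
    if b is not None:
        out = out + b.data.reshape((-1,) + (1,) * nd)

    def bw(g):
        # weight gradient: correlate input patches with the output gradient
        gw = np.tensordot(g, patches, axes=(list(range(1, nd + 1)),
                                            list(range(1, nd + 1))))
        # input gradient: full correlation of g with flipped kernels
        gp = np.pad(g, [(0, 0)] + pads)
        gpat = sliding_window_view(gp, ker, axis=tuple(range(1, nd + 1)))
        wflip = np.flip(w.data, axis=tuple(range(2, 2 + nd)))
        gx = np.tensordot(wflip.transpose((1, 0) + tuple(range(2, 2 + nd))),
                          gpat, axes=(axes_w, axes_p))
        gb = None if b is None else g.sum(axis=tuple(range(1, nd + 1)))
        return (gx, gw) if b is None else (gx, gw, gb)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out, parents=parents, backward=bw)


def avg_pool(x: Tensor, factor: int = 2) -> Tensor:
    """Average pooling by an integer factor on every spatial axis."""
    nd = x.ndim - 1
    sp = x.shape[1:]
    if any(s % factor for s in sp):
        raise ValueError(f"spatial dims {sp} not divisible by {factor}")
    newshape = [x.shape[0]]
    for s in sp:
        newshape += [s // factor, factor]
    perm = [0] + list(range(1, 2 * nd + 1, 2)) + list(range(2, 2 * nd + 1, 2))
    xr = x.data.reshape(newshape).transpose(perm)
    red = tuple(range(nd + 1, 2 * nd + 1))
    out = xr.mean(axis=red)

    def bw(g):
        gg = g / (factor ** nd)
        for ax in range(1, nd + 1):
            gg = np.repeat(gg, factor, axis=ax)
        return (gg,)

    return Tensor(out, parents=(x,), backward=bw)


def upsample_nearest(x: Tensor, factor: int = 2) -> Tensor:
    nd = x.ndim - 1
    out = x.data
    for ax in range(1, nd + 1):
        out = np.repeat(out, factor, axis=ax)

    def bw(g):
        gg = g
        for ax in range(1, nd + 1):
            s = gg.shape
            gg = gg.reshape(s[:ax] + (s[ax] // factor, factor) + s[ax + 1:])
            gg = gg.sum(axis=ax + 1)
        return (gg,)

    return Tensor(out, parents=(x,), backward=bw)


def group_norm(x: Tensor, gamma: Tensor, beta: Tensor, n_groups: int,
               eps: float = 1e-5) -> Tensor:
    """Group normalization over (channel-group, spatial), composed from
    differentiable primitives so the gradient comes for free."""
    C = x.shape[0]
    if C % n_groups:
        raise ValueError(f"{C} channels not divisible into {n_groups} groups")
    sp = x.shape[1:]
    xg = x.reshape((n_groups, C // n_groups) + sp)
    axes = tuple(range(1, xg.ndim))
    m = xg.mean(axis=axes, keepdims=True)
    var = ((xg - m) ** 2.0).mean(axis=axes, keepdims=True)
    xn = (xg - m) * ((var + eps) ** -0.5)
    xn = xn.reshape((C,) + sp)
    shape = (C,) + (1,) * len(sp)
    return xn * gamma.reshape(shape) + beta.reshape(shape)


def custom_op(inputs, forward_out: np.ndarray, backward_fn) -> Tensor:
    """Insert an externally computed result with a hand-written VJP.

    ``backward_fn(upstream) -> tuple of gradients`` aligned with ``inputs``.
    """
    return Tensor(forward_out, parents=tuple(inputs), backward=backward_fn)
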