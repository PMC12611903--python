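"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This module provides exactly the primitives the segmentation networks need:
dense/convolutional layers (2D and 3D, standard and depthwise-separable),
factor-2 max pooling, transposed-convolution upsampling, instance
normalization, pointwise nonlinearities, an Adam optimizer and a
reduce-on-plateau learning-rate scheduler.  Everything runs in float32 on a
single CPU and is deterministic for a fixed RNG.

Gradient correctness of every primitive is checked against central finite
differences in the test suite.
"""

from __future__ import annotations

import json
from typing import Callable, Sequence

import numpy as np
from numba import njit as _njit
from numpy.lib.stride_tricks import sliding_window_view

_F32 = np.float32


def _as_array(x) -> np.ndarray:
    a = np.asarray(x)
    if a.dtype != _F32 and np.issubdtype(a.dtype, np.floating):
        a = a.astype(_F32)
    elif not np.issubdtype(a.dtype, np.floating):
        a = a.astype(_F32)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd_extra = grad.ndim - len(shape)
    if nd_extra > 0:
        grad = grad.sum(axis=tuple(range(nd_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: tuple = (), _backward: Callable | None = None):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    # -- infrastructure ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(_F32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        o = self._coerce(other)
        out = Tensor(self.data + o.data, self.requires_grad or o.requires_grad,
                     (self, o))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accum(_unbroadcast(g, self.data.shape))
            if o.requires_grad or o._parents:
                o._accum(_unbroadcast(g, o.data.shape))
        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        o = self._coerce(other)
        out = Tensor(self.data * o.data, self.requires_grad or o.requires_grad,
                     (self, o))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accum(_unbroadcast(g * o.data, self.data.shape))
            if o.requires_grad or o._parents:
                o._accum(_unbroadcast(g * self.data, o.data.shape))
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __truediv__(self, other):
        o = self._coerce(other)
        out = Tensor(self.data / o.data, self.requires_grad or o.requires_grad,
                     (self, o))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accum(_unbroadcast(g / o.data, self.data.shape))
            if o.requires_grad or o._parents:
                o._accum(_unbroadcast(-g * self.data / (o.data * o.data),
                                      o.data.shape))
        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    # -- pointwise ---------------------------------------------------------

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, True, (self,))

        def bw(g):
            self._accum(g * mask)
        out._backward = bw
        return out

    def sigmoid(self):
        x = self.data
        y = np.empty_like(x)
        pos = x >= 0
        y[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        y[~pos] = ex / (1.0 + ex)
        out = Tensor(y, True, (self,))

        def bw(g):
            self._accum(g * y * (1.0 - y))
        out._backward = bw
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, True, (self,))

        def bw(g):
            self._accum(g * (1.0 - y * y))
        out._backward = bw
        return out

    def sqrt(self):
        y = np.sqrt(self.data)
        out = Tensor(y, True, (self,))

        def bw(g):
            self._accum(g * 0.5 / y)
        out._backward = bw
        return out

    # -- reductions / shaping ----------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), True, (self,))

        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).astype(_F32))
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).astype(_F32))
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def amax(self, axis: int):
        """Max along one axis; ties route the gradient to the first argmax."""
        idx = np.argmax(self.data, axis=axis)
        y = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis)
        out = Tensor(np.squeeze(y, axis=axis), True, (self,))

        def bw(g):
            gx = np.zeros_like(self.data)
            np.put_along_axis(gx, np.expand_dims(idx, axis),
                              np.expand_dims(g, axis), axis=axis)
            self._accum(gx)
        out._backward = bw
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), True, (self,))

        def bw(g):
            self._accum(g.reshape(self.data.shape))
        out._backward = bw
        return out

    def matmul(self, other: "Tensor"):
        o = self._coerce(other)
        out = Tensor(self.data @ o.data, True, (self, o))

        def bw(g):
            self._accum(g @ o.data.swapaxes(-1, -2))
            o._accum(self.data.swapaxes(-1, -2) @ g)
        out._backward = bw
        return out

    def take_channel(self, index: int):
        """Select one channel from an (N, C, ...) tensor, keeping axis 1."""
        out = Tensor(self.data[:, index:index + 1], True, (self,))

        def bw(g):
            gx = np.zeros_like(self.data)
            gx[:, index:index + 1] = g
            self._accum(gx)
        out._backward = bw
        return out


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), True, tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, gpart in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(gpart)
    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# Convolution primitives (stride 1, "same" zero padding, odd kernels)
# ---------------------------------------------------------------------------

def _pad_spatial(x: np.ndarray, p: int, nd: int) -> np.ndarray:
    if p == 0:
        return x
    pad = [(0, 0), (0, 0)] + [(p, p)] * nd
    return np.pad(x, pad)


# direct (loop) 3D kernels, JIT-compiled once per process; these avoid the
# large window materialization that an im2col path needs
@_njit(cache=True, fastmath=True)
def _nb_conv3_fwd(xp, w, y):  # xp (N,C,Dp,Hp,Wp), w (O,C,k,k,k)
    n_b, c_out = y.shape[0], y.shape[1]
    c_in, k = w.shape[1], w.shape[2]
    wd = y.shape[4]
    for n in range(n_b):
        for o in range(c_out):
            for d in range(y.shape[2]):
                for h in range(y.shape[3]):
                    for v in range(wd):
                        y[n, o, d, h, v] = 0.0
                    for c in range(c_in):
                        for i in range(k):
                            for j in range(k):
                                for l in range(k):
                                    wv = w[o, c, i, j, l]
                                    for v in range(wd):
                                        y[n, o, d, h, v] += wv * \
                                            xp[n, c, d + i, h + j, v + l]


@_njit(cache=True, fastmath=True)
def _nb_conv3_gw(xp, g, gw):  # g (N,O,D,H,W), gw (O,C,k,k,k)
    n_b, c_out = g.shape[0], g.shape[1]
    c_in, k = gw.shape[1], gw.shape[2]
    wd = g.shape[4]
    for o in range(c_out):
        for c in range(c_in):
            for i in range(k):
                for j in range(k):
                    for l in range(k):
                        s = 0.0
                        for n in range(n_b):
                            for d in range(g.shape[2]):
                                for h in range(g.shape[3]):
                                    for v in range(wd):
                                        s += g[n, o, d, h, v] * \
                                            xp[n, c, d + i, h + j, v + l]
                        gw[o, c, i, j, l] += s


@_njit(cache=True, fastmath=True)
def _nb_dw3_fwd(xp, w, y):  # xp (N,C,Dp,Hp,Wp), w (C,k,k,k)
    n_b, c_ch = y.shape[0], y.shape[1]
    k = w.shape[1]
    wd = y.shape[4]
    for n in range(n_b):
        for c in range(c_ch):
            for d in range(y.shape[2]):
                for h in range(y.shape[3]):
                    for v in range(wd):
                        y[n, c, d, h, v] = 0.0
                    for i in range(k):
                        for j in range(k):
                            for l in range(k):
                                wv = w[c, i, j, l]
                                for v in range(wd):
                                    y[n, c, d, h, v] += wv * \
                                        xp[n, c, d + i, h + j, v + l]


@_njit(cache=True, fastmath=True)
def _nb_dw3_gw(xp, g, gw):  # g (N,C,D,H,W), gw (C,k,k,k)
    n_b, c_ch = g.shape[0], g.shape[1]
    k = gw.shape[1]
    wd = g.shape[4]
    for c in range(c_ch):
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    s = 0.0
                    for n in range(n_b):
                        for d in range(g.shape[2]):
                            for h in range(g.shape[3]):
                                for v in range(wd):
                                    s += g[n, c, d, h, v] * \
                                        xp[n, c, d + i, h + j, v + l]
                    gw[c, i, j, l] += s


@_njit(cache=True, fastmath=True)
def _nb_conv2_fwd(xp, w, y):  # xp (N,C,Hp,Wp), w (O,C,k,k)
    n_b, c_out = y.shape[0], y.shape[1]
    c_in, k = w.shape[1], w.shape[2]
    wd = y.shape[3]
    for n in range(n_b):
        for o in range(c_out):
            for h in range(y.shape[2]):
                for v in range(wd):
                    y[n, o, h, v] = 0.0
                for c in range(c_in):
                    for i in range(k):
                        for j in range(k):
                            wv = w[o, c, i, j]
                            for v in range(wd):
                                y[n, o, h, v] += wv * xp[n, c, h + i, v + j]


@_njit(cache=True, fastmath=True)
def _nb_conv2_gw(xp, g, gw):  # g (N,O,H,W), gw (O,C,k,k)
    n_b, c_out = g.shape[0], g.shape[1]
    c_in, k = gw.shape[1], gw.shape[2]
    wd = g.shape[3]
    for o in range(c_out):
        for c in range(c_in):
            for i in range(k):
                for j in range(k):
                    s = 0.0
                    for n in range(n_b):
                        for h in range(g.shape[2]):
                            for v in range(wd):
                                s += g[n, o, h, v] * xp[n, c, h + i, v + j]
                    gw[o, c, i, j] += s


def _conv_direct_data(x: np.ndarray, w: np.ndarray, nd: int) -> np.ndarray:
    """Direct same-padded correlation via the JIT kernels."""
    xp = _pad_spatial(np.ascontiguousarray(x), w.shape[2] // 2, nd)
    y = np.empty((x.shape[0], w.shape[0]) + x.shape[2:], dtype=_F32)
    if nd == 3:
        _nb_conv3_fwd(xp, np.ascontiguousarray(w), y)
    else:
        _nb_conv2_fwd(xp, np.ascontiguousarray(w), y)
    return y


def _pointwise_data(x: np.ndarray, w2: np.ndarray) -> np.ndarray:
    # x (N,Cin,*sp) , w2 (Cout,Cin) -> (N,Cout,*sp)
    y = np.tensordot(x, w2, axes=([1], [1]))
    return np.moveaxis(y, -1, 1)


def conv_nd(x: Tensor, w: Tensor, b: Tensor | None, nd: int) -> Tensor:
    """Same-padded stride-1 convolution, x (N,Cin,*sp), w (Cout,Cin,*k).

    k=1 runs as a channel-mixing matmul; larger kernels run through the
    direct JIT path (no window materialization).
    """
    parents = (x, w) if b is None else (x, w, b)
    k = w.data.shape[2]
    c_out, c_in = w.data.shape[:2]
    if k == 1:
        w2 = w.data.reshape(c_out, c_in)
        y = _pointwise_data(x.data, w2)
    else:
        y = _conv_direct_data(x.data, w.data, nd)
    if b is not None:
        y = y + b.data.reshape((1, -1) + (1,) * nd)
    out = Tensor(y, True, parents)

    def bw(g):
        sp_axes = tuple(range(2, 2 + nd))
        if k == 1:
            w2 = w.data.reshape(c_out, c_in)
            gw = np.tensordot(g, x.data, axes=((0,) + sp_axes, (0,) + sp_axes))
            w._accum(gw.reshape(w.data.shape))
            x._accum(_pointwise_data(g, w2.T))
        else:
            flip = w.data[(slice(None), slice(None))
                          + (slice(None, None, -1),) * nd]
            xp = _pad_spatial(np.ascontiguousarray(x.data), k // 2, nd)
            gw = np.zeros_like(w.data)
            gc = np.ascontiguousarray(g)
            if nd == 3:
                _nb_conv3_gw(xp, gc, gw)
            else:
                _nb_conv2_gw(xp, gc, gw)
            w._accum(gw)
            x._accum(_conv_direct_data(g, flip.swapaxes(0, 1), nd))
        if b is not None:
            b._accum(g.sum(axis=(0,) + tuple(range(2, 2 + nd))))
    out._backward = bw
    return out


def _im2col_chan(x: np.ndarray, kshape, nd: int) -> np.ndarray:
    """Per-channel column tensor (C, N*prod(sp), prod(k)) of same-padded
    windows; the workhorse of the depthwise paths."""
    k = kshape[0]
    xp = _pad_spatial(x, k // 2, nd)
    win = sliding_window_view(xp, kshape, axis=tuple(range(2, 2 + nd)))
    win = np.moveaxis(win, 1, 0)  # (C, N, *sp, *k)
    c = x.shape[1]
    ns = x.shape[0] * int(np.prod(x.shape[2:]))
    return np.ascontiguousarray(win).reshape(c, ns, -1)


def _dw3_data(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    xp = _pad_spatial(np.ascontiguousarray(x), w.shape[1] // 2, 3)
    y = np.empty(x.shape, dtype=_F32)
    _nb_dw3_fwd(xp, np.ascontiguousarray(w), y)
    return y


def depthwise_conv_nd(x: Tensor, w: Tensor, b: Tensor | None, nd: int) -> Tensor:
    """Channel-wise spatial filtering: x (N,C,*sp), w (C,*k)."""
    parents = (x, w) if b is None else (x, w, b)
    n, c = x.data.shape[:2]
    sp = x.data.shape[2:]
    kshape = w.data.shape[1:]
    if nd == 3:
        y = _dw3_data(x.data, w.data)
    else:
        cols = _im2col_chan(x.data, kshape, nd)      # (C, N*S, K)
        wflat = w.data.reshape(c, -1)
        y = np.empty((c, n * int(np.prod(sp))), dtype=_F32)
        for ch in range(c):
            y[ch] = cols[ch] @ wflat[ch]
        y = np.ascontiguousarray(np.moveaxis(y.reshape((c, n) + sp), 0, 1))
    if b is not None:
        y = y + b.data.reshape((1, -1) + (1,) * nd)
    out = Tensor(y, True, parents)

    def bw(g):
        flip_w = w.data[(slice(None),) + (slice(None, None, -1),) * nd]
        if nd == 3:
            xp = _pad_spatial(np.ascontiguousarray(x.data),
                              kshape[0] // 2, 3)
            gw = np.zeros_like(w.data)
            _nb_dw3_gw(xp, np.ascontiguousarray(g), gw)
            w._accum(gw)
            x._accum(_dw3_data(g, flip_w))
        else:
            gflat = np.moveaxis(g, 1, 0).reshape(c, -1)
            wflat = w.data.reshape(c, -1)
            gw = np.empty_like(wflat)
            for ch in range(c):
                gw[ch] = cols[ch].T @ gflat[ch]
            w._accum(gw.reshape(w.data.shape))
            gcols = _im2col_chan(g, kshape, nd)
            gx = np.empty_like(gflat)
            for ch in range(c):
                gx[ch] = gcols[ch] @ wflat[ch, ::-1]
            x._accum(np.moveaxis(gx.reshape((c, n) + sp), 0, 1))
        if b is not None:
            b._accum(g.sum(axis=(0,) + tuple(range(2, 2 + nd))))
    out._backward = bw
    return out


def maxpool2_nd(x: Tensor, nd: int) -> Tensor:
    """Factor-2 max pooling; spatial sizes must be even."""
    n, c = x.data.shape[:2]
    sp = x.data.shape[2:]
    if any(s % 2 for s in sp):
        raise ValueError(f"maxpool2 needs even spatial sizes, got {sp}")
    newshape = (n, c) + sum(((s // 2, 2) for s in sp), ())
    xr = x.data.reshape(newshape)
    # move the factor-2 axes to the end and flatten them
    order = (0, 1) + tuple(2 + 2 * i for i in range(nd)) + \
        tuple(3 + 2 * i for i in range(nd))
    xt = xr.transpose(order).reshape(
        (n, c) + tuple(s // 2 for s in sp) + (2 ** nd,))
    idx = np.argmax(xt, axis=-1)
    y = np.take_along_axis(xt, idx[..., None], axis=-1)[..., 0]
    out = Tensor(y, True, (x,))

    def bw(g):
        gt = np.zeros_like(xt)
        np.put_along_axis(gt, idx[..., None], g[..., None], axis=-1)
        inv = np.argsort(order)
        gx = gt.reshape((n, c) + tuple(s // 2 for s in sp) + (2,) * nd)
        gx = gx.transpose(inv).reshape(x.data.shape)
        x._accum(gx)
    out._backward = bw
    return out


def conv_transpose2_nd(x: Tensor, w: Tensor, nd: int) -> Tensor:
    """Kernel-2, stride-2 transposed convolution (doubles spatial size).

    w has shape (Cin, Cout, 2, ..., 2).
    """
    n = x.data.shape[0]
    sp = x.data.shape[2:]
    cout = w.data.shape[1]
    t = np.tensordot(x.data, w.data, axes=([1], [0]))
    # t: (N, *sp, Cout, 2...2) -> interleave
    order = (0, 1 + nd) + sum(((1 + i, 2 + nd + i) for i in range(nd)), ())
    y = t.transpose(order).reshape((n, cout) + tuple(2 * s for s in sp))
    out = Tensor(y, True, (x, w))

    def bw(g):
        gb = g.reshape((n, cout) + sum(((s, 2) for s in sp), ()))
        # back to (N, *sp, Cout, 2...2)
        inv = np.argsort(order)
        gt = gb.transpose(inv)
        sp_axes = tuple(range(1, 1 + nd))
        w._accum(np.tensordot(x.data, gt, axes=((0,) + tuple(range(2, 2 + nd)),
                                                (0,) + sp_axes)))
        gx = np.tensordot(gt, w.data,
                          axes=((1 + nd,) + tuple(range(2 + nd, 2 + 2 * nd)),
                                (1,) + tuple(range(2, 2 + nd))))
        x._accum(np.moveaxis(gx, -1, 1))
    out._backward = bw
    return out


def upsample_nearest2_nd(x: Tensor, nd: int) -> Tensor:
    y = x.data
    for ax in range(2, 2 + nd):
        y = np.repeat(y, 2, axis=ax)
    out = Tensor(y, True, (x,))

    def bw(g):
        n, c = x.data.shape[:2]
        sp = x.data.shape[2:]
        gr = g.reshape((n, c) + sum(((s, 2) for s in sp), ()))
        gx = gr.sum(axis=tuple(3 + 2 * i for i in range(nd)))
        x._accum(gx)
    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class Module:
    """Base class: named parameter collection + (de)serialisation."""

    def parameters(self) -> list[Tensor]:
        out = []
        for v in vars(self).values():
            out.extend(_collect(v))
        return out

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for k, v in vars(self).items():
            _collect_named(v, f"{prefix}{k}", out)
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: t.data for k, t in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = self.named_parameters()
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state mismatch on keys: {sorted(missing)}")
        for k, t in own.items():
            if t.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            t.data = state[k].astype(_F32)

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def _collect(v) -> list[Tensor]:
    if isinstance(v, Tensor):
        return [v] if v.requires_grad else []
    if isinstance(v, Module):
        return v.parameters()
    if isinstance(v, (list, tuple)):
        out = []
        for item in v:
            out.extend(_collect(item))
        return out
    return []


def _collect_named(v, name: str, out: dict) -> None:
    if isinstance(v, Tensor):
        if v.requires_grad:
            out[name] = v
    elif isinstance(v, Module):
        out.update(v.named_parameters(prefix=name + "."))
    elif isinstance(v, (list, tuple)):
        for i, item in enumerate(v):
            _collect_named(item, f"{name}.{i}", out)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    std = np.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, std, size=shape), requires_grad=True)


class Conv(Module):
    def __init__(self, rng, c_in: int, c_out: int, k: int, nd: int,
                 bias: bool = True):
        self.nd = nd
        self.w = _he_init(rng, (c_out, c_in) + (k,) * nd, c_in * k ** nd)
        self.b = Tensor(np.zeros(c_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv_nd(x, self.w, self.b, self.nd)


class DepthwiseSeparableConv(Module):
    """k^nd depthwise filter per channel, then 1x..x1 pointwise mixing."""

    def __init__(self, rng, c_in: int, c_out: int, k: int, nd: int,
                 bias: bool = True):
        self.nd = nd
        self.dw = _he_init(rng, (c_in,) + (k,) * nd, k ** nd)
        self.dw_b = Tensor(np.zeros(c_in), requires_grad=True) if bias else None
        self.pw = _he_init(rng, (c_out, c_in) + (1,) * nd, c_in)
        self.pw_b = Tensor(np.zeros(c_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        h = depthwise_conv_nd(x, self.dw, self.dw_b, self.nd)
        return conv_nd(h, self.pw, self.pw_b, self.nd)


class InstanceNorm(Module):
    """Per-sample, per-channel normalization with learnable affine."""

    def __init__(self, channels: int, nd: int, eps: float = 1e-5):
        self.nd = nd
        self.eps = eps
        self.gamma = Tensor(np.ones((1, channels) + (1,) * nd),
                            requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels) + (1,) * nd),
                           requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        sp = tuple(range(2, 2 + self.nd))
        m = x.mean(axis=sp, keepdims=True)
        xc = x - m
        v = (xc * xc).mean(axis=sp, keepdims=True)
        xhat = xc / (v + self.eps).sqrt()
        return xhat * self.gamma + self.beta


class Linear(Module):
    def __init__(self, rng, n_in: int, n_out: int, bias: bool = True):
        self.w = _he_init(rng, (n_in, n_out), n_in)
        self.b = Tensor(np.zeros(n_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x.matmul(self.w)
        return y + self.b if self.b is not None else y


class ConvTranspose2(Module):
    def __init__(self, rng, c_in: int, c_out: int, nd: int):
        self.nd = nd
        self.w = _he_init(rng, (c_in, c_out) + (2,) * nd, c_in * 2 ** nd)

    def __call__(self, x: Tensor) -> Tensor:
        return conv_transpose2_nd(x, self.w, self.nd)


# ---------------------------------------------------------------------------
# Optimization
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params: Sequence[Tensor], lr: float = 2e-4,
                 beta1: float = 0.5, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
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
            v += (1 - b2) * g * g
            p.data -= (self.lr * (m / bc1) /
                       (np.sqrt(v / bc2) + self.eps)).astype(_F32)


class ReduceLROnPlateau:
    """Halve the optimizer learning rate after `patience` epochs without a
    new minimum of the monitored metric (strict improvement)."""

    def __init__(self, optimizer: Adam, patience: int = 10,
                 factor: float = 0.5, min_delta: float = 0.0):
        self.opt = optimizer
        self.patience = int(patience)
        self.factor = float(factor)
        self.min_delta = float(min_delta)
        self.best = np.inf
        self.bad_epochs = 0

    @property
    def lr(self) -> float:
        return self.opt.lr

    def step(self, metric: float) -> None:
        if metric < self.best - self.min_delta:
            self.best = metric
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs >= self.patience:
                self.opt.lr *= self.factor
                self.bad_epochs = 0


# ---------------------------------------------------------------------------
# Checkpoint I/O
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: Module, config: dict) -> None:
    """Persist weights plus the architecture config needed to rebuild."""
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    arrays["__config__"] = np.frombuffer(
        json.dumps(config).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[dict, dict]:
    """Return (config dict, state dict) from a saved checkpoint."""
    with np.load(path) as z:
        config = json.loads(z["__config__"].tobytes().decode())
        state = {k[len("param/"):]: z[k] for k in z.files
                 if k.startswith("param/")}
    return config, state
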