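"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operations the two prediction branches need:
broadcast arithmetic, matmul (with batch broadcasting), ReLU/tanh/exp/log,
reductions, reshape/transpose/flip, 2-D zero padding, stride-1 convolution,
stride-1 max-pooling and a numerically stable log-sum-exp (from which
softmax and cross-entropy are composed).  Transposed convolution is built
by composition: pad + flipped-kernel convolution.

All tensors are float64.  Gradients are accumulated by topological-order
backward passes over a dynamically recorded graph.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor", "tensor", "add", "sub", "mul", "div", "neg", "matmul",
    "relu", "tanh", "exp", "log", "tsum", "tmean", "logsumexp", "softmax",
    "reshape", "swapaxes", "flip", "concat", "stack", "pad2d", "conv2d",
    "conv_transpose2d", "maxpool2d", "linear", "cross_entropy_with_logits",
    "Adam", "grad_check",
]


class Tensor:
    """A numpy array plus an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")
    __array_priority__ = 100.0

    def __init__(self, data, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph machinery ---------------------------------------------------

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self):
        self.grad = None

    # -- operator sugar ----------------------------------------------------

    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, other)


def tensor(data, requires_grad=False):
    return Tensor(data, requires_grad)


def _wrap(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward):
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g, shape):
    """Sum gradient g down to the given (broadcast-source) shape."""
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


# -- arithmetic -----------------------------------------------------------


def add(a, b):
    a, b = _wrap(a), _wrap(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    return _make(out_data, (a, b), backward)


def sub(a, b):
    a, b = _wrap(a), _wrap(b)
    out_data = a.data - b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g, b.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b):
    a, b = _wrap(a), _wrap(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _make(out_data, (a, b), backward)


def div(a, b):
    a, b = _wrap(a), _wrap(b)
    out_data = a.data / b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g / b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g * a.data / (b.data ** 2), b.shape))

    return _make(out_data, (a, b), backward)


def neg(a):
    a = _wrap(a)

    def backward(g):
        if a.requires_grad:
            a._accumulate(-g)

    return _make(-a.data, (a,), backward)


def matmul(a, b):
    """Matrix product with numpy batch-broadcast semantics."""
    a, b = _wrap(a), _wrap(b)
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            if b.data.ndim == 1:
                ga = np.multiply.outer(g, b.data) if a.data.ndim > 1 else g * b.data
                if a.data.ndim > 2:
                    ga = ga.reshape(a.data.shape)
            else:
                gg = g[..., None, :] if a.data.ndim == 1 else g
                ga = gg @ np.swapaxes(b.data, -1, -2)
                if a.data.ndim == 1:
                    ga = ga.reshape(a.data.shape)
            a._accumulate(_unbroadcast(ga, a.shape))
        if b.requires_grad:
            if a.data.ndim == 1:
                gb = np.multiply.outer(a.data, g) if b.data.ndim > 1 else g * a.data
            elif b.data.ndim == 1:
                gb = (np.swapaxes(a.data, -1, -2) @ g[..., None])[..., 0]
                gb = _unbroadcast(gb, b.shape) if gb.shape != b.shape else gb
            else:
                gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate(_unbroadcast(gb, b.shape))

    return _make(out_data, (a, b), backward)


# -- activations ----------------------------------------------------------


def relu(a):
    a = _wrap(a)
    mask = a.data > 0

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * mask)

    return _make(a.data * mask, (a,), backward)


def tanh(a):
    a = _wrap(a)
    t = np.tanh(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * (1.0 - t * t))

    return _make(t, (a,), backward)


def exp(a):
    a = _wrap(a)
    e = np.exp(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * e)

    return _make(e, (a,), backward)


def log(a):
    a = _wrap(a)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g / a.data)

    return _make(np.log(a.data), (a,), backward)


# -- reductions -----------------------------------------------------------


def tsum(a, axis=None, keepdims=False):
    a = _wrap(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if not a.requires_grad:
            return
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.shape).copy())
            return
        gg = g
        if not keepdims:
            gg = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(gg, a.shape).copy())

    return _make(out_data, (a,), backward)


def tmean(a, axis=None, keepdims=False):
    a = _wrap(a)
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def logsumexp(a, axis=-1, keepdims=False):
    a = _wrap(a)
    m = a.data.max(axis=axis, keepdims=True)
    e = np.exp(a.data - m)
    s = e.sum(axis=axis, keepdims=True)
    out_data = np.log(s) + m
    soft = e / s
    if not keepdims:
        out_data = np.squeeze(out_data, axis=axis)

    def backward(g):
        if not a.requires_grad:
            return
        gg = g if keepdims else np.expand_dims(g, axis)
        a._accumulate(gg * soft)

    return _make(out_data, (a,), backward)


def softmax(a, axis=-1):
    return exp(sub(a, logsumexp(a, axis=axis, keepdims=True)))


# -- shape ops ------------------------------------------------------------


def reshape(a, shape):
    a = _wrap(a)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.reshape(a.shape))

    return _make(a.data.reshape(shape), (a,), backward)


def swapaxes(a, ax1, ax2):
    a = _wrap(a)

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.swapaxes(g, ax1, ax2))

    return _make(np.swapaxes(a.data, ax1, ax2), (a,), backward)


def flip(a, axis):
    a = _wrap(a)

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.flip(g, axis))

    return _make(np.flip(a.data, axis).copy(), (a,), backward)


def concat(tensors, axis=0):
    tensors = [_wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(p)

    return _make(out_data, tuple(tensors), backward)


def stack(tensors, axis=0):
    tensors = [_wrap(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(np.take(g, i, axis=axis))

    return _make(out_data, tuple(tensors), backward)


def pad2d(a, pad_h, pad_w):
    """Zero-pad the trailing two axes by pad_h / pad_w on each side."""
    a = _wrap(a)
    width = [(0, 0)] * (a.ndim - 2) + [(pad_h, pad_h), (pad_w, pad_w)]
    out_data = np.pad(a.data, width)
    H, W = a.data.shape[-2], a.data.shape[-1]

    def backward(g):
        if a.requires_grad:
            sl = (Ellipsis, slice(pad_h, pad_h + H), slice(pad_w, pad_w + W))
            a._accumulate(g[sl])

    return _make(out_data, (a,), backward)


# -- convolution / pooling (stride 1) -------------------------------------


def _conv_forward(x, w):
    # x: (B, Cin, H, W), w: (Cout, Cin, kh, kw) -> (B, Cout, H-kh+1, W-kw+1)
    kh, kw = w.shape[-2], w.shape[-1]
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))  # (B,Cin,H',W',kh,kw)
    out = np.tensordot(win, w, axes=([1, 4, 5], [1, 2, 3]))  # (B,H',W',Cout)
    return np.ascontiguousarray(np.moveaxis(out, -1, 1))


def conv2d(x, w, b=None, padding=0):
    """Stride-1 2-D cross-correlation over (B, Cin, H, W)."""
    x, w = _wrap(x), _wrap(w)
    if padding:
        x = pad2d(x, padding, padding)
    kh, kw = w.data.shape[-2], w.data.shape[-1]
    if kh > x.data.shape[-2] or kw > x.data.shape[-1]:
        raise ValueError(
            f"conv kernel {kh}x{kw} larger than input "
            f"{x.data.shape[-2]}x{x.data.shape[-1]}"
        )
    out_data = _conv_forward(x.data, w.data)

    def backward(g):
        if x.requires_grad:
            # full correlation of g with spatially flipped kernels
            gp = np.pad(g, [(0, 0), (0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1)])
            wf = np.flip(w.data, (-1, -2)).swapaxes(0, 1)  # (Cin,Cout,kh,kw)
            x._accumulate(_conv_forward(gp, wf))
        if w.requires_grad:
            win = sliding_window_view(x.data, (kh, kw), axis=(2, 3))
            gw = np.tensordot(g, win, axes=([0, 2, 3], [0, 2, 3]))
            w._accumulate(gw)  # (Cout, Cin, kh, kw)

    out = _make(out_data, (x, w), backward)
    if b is not None:
        out = add(out, reshape(_wrap(b), (1, -1, 1, 1)))
    return out


def conv_transpose2d(x, w, b=None, padding=0):
    """Stride-1 transposed convolution; w has shape (Cin, Cout, kh, kw).

    Output spatial size is ``in + k - 1 - 2*padding``.  Built by composition
    as a flipped-kernel convolution of the zero-padded input.
    """
    x, w = _wrap(x), _wrap(w)
    kh, kw = w.data.shape[-2], w.data.shape[-1]
    ph, pw = kh - 1 - padding, kw - 1 - padding
    if ph < 0 or pw < 0:
        raise ValueError("conv_transpose2d padding may not exceed kernel-1")
    xp = pad2d(x, ph, pw)
    wf = swapaxes(flip(w, (-1, -2)), 0, 1)  # (Cout, Cin, kh, kw)
    return conv2d(xp, wf, b=b, padding=0)


def maxpool2d(x, kh, kw):
    """Stride-1 max pooling without padding over the trailing two axes."""
    x = _wrap(x)
    H, W = x.data.shape[-2], x.data.shape[-1]
    if kh > H or kw > W:
        raise ValueError(f"pool kernel {kh}x{kw} larger than input {H}x{W}")
    win = sliding_window_view(x.data, (kh, kw), axis=(-2, -1))
    flat = win.reshape(win.shape[:-2] + (kh * kw,))
    arg = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        gx = np.zeros_like(x.data)
        oh, ow = out_data.shape[-2], out_data.shape[-1]
        idx = np.indices(out_data.shape)
        di, dj = np.unravel_index(arg, (kh, kw))
        rows = idx[-2] + di
        cols = idx[-1] + dj
        lead = tuple(idx[i] for i in range(out_data.ndim - 2))
        np.add.at(gx, lead + (rows, cols), g)
        del oh, ow
        x._accumulate(gx)

    return _make(out_data, (x,), backward)


# -- composites -----------------------------------------------------------


def linear(x, W, b):
    """x @ W.T + b with W of shape (out, in)."""
    return add(matmul(x, swapaxes(_wrap(W), -1, -2)), b)


def cross_entropy_with_logits(logits, onehot):
    """Summed cross-entropy  -sum y*log softmax(logits)  over the batch."""
    logp = sub(logits, logsumexp(logits, axis=-1, keepdims=True))
    return neg(tsum(mul(_wrap(onehot), logp)))


# -- optimisation ---------------------------------------------------------


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def grad_check(fn, params, eps=1e-6):
    """Max relative error between backprop and central finite differences.

    ``fn()`` must rebuild the graph and return a scalar Tensor each call.
    """
    loss = fn()
    for p in params:
        p.grad = None
    loss.backward()
    worst = 0.0
    for p in params:
        g = p.grad if p.grad is not None else np.zeros_like(p.data)
        it = np.nditer(p.data, flags=["multi_index"])
        while not it.finished:
            ix = it.multi_index
            orig = p.data[ix]
            p.data[ix] = orig + eps
            lp = fn().data.item()
            p.data[ix] = orig - eps
            lm = fn().data.item()
            p.data[ix] = orig
            num = (lp - lm) / (2 * eps)
            denom = max(1.0, abs(num), abs(g[ix]))
            worst = max(worst, abs(num - g[ix]) / denom)
            it.iternext()
    return worst
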