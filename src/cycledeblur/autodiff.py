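"""Reverse-mode automatic differentiation on numpy arrays.

The engine is deliberately small: a :class:`Tensor` wraps an ``ndarray`` and
records, for every primitive operation, the parent tensors together with
vector-Jacobian-product (vjp) closures.  The closures are themselves written
in terms of traced primitives, so calling :func:`grad` with
``create_graph=True`` yields a gradient that is again a differentiable graph
node.  That property is what makes the WGAN gradient penalty trainable: the
penalty is a function of the critic's input-gradient, and its parameter
gradient is a second derivative through the critic.

Only the primitives the networks need are provided.  Convolutions are not
primitives; they are composed from ``im2col``/``col2im`` (a transpose pair of
linear gather/scatter ops) and a 2-D matmul, which keeps every vjp exact and
closed under differentiation.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

from . import _gather

DTYPE = np.float32

_GRAD_ENABLED = [True]


@contextmanager
def no_grad():
    """Disable graph recording inside the block."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def _recording() -> bool:
    return _GRAD_ENABLED[-1]


class Tensor:
    """An ndarray plus the tape entry that produced it."""

    __slots__ = ("data", "_parents", "requires_grad")

    def __init__(self, data, parents=(), requires_grad=False):
        self.data = np.asarray(data, dtype=DTYPE)
        self._parents = parents
        self.requires_grad = requires_grad or bool(parents)

    # -- convenience -------------------------------------------------
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

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    # -- operators ---------------------------------------------------
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

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, c):
        return power(self, c)

    def __getitem__(self, idx):
        return getitem(self, idx)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, pairs) -> Tensor:
    """Build an op output; ``pairs`` is a list of (parent, vjp) tuples."""
    if _recording():
        live = tuple((p, fn) for p, fn in pairs if p.requires_grad)
        if live:
            return Tensor(data, live)
    return Tensor(data)


def _unbroadcast(g: Tensor, shape) -> Tensor:
    """Reduce a broadcast cotangent back to ``shape``."""
    if g.shape == tuple(shape):
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = sum_(g, axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and g.shape[i] != 1)
    if axes:
        g = sum_(g, axis=axes, keepdims=True)
    return reshape(g, shape)


# ---------------------------------------------------------------------------
# arithmetic primitives
# ---------------------------------------------------------------------------

def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return _make(a.data + b.data,
                 [(a, lambda g: _unbroadcast(g, a.shape)),
                  (b, lambda g: _unbroadcast(g, b.shape))])


def sub(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return _make(a.data - b.data,
                 [(a, lambda g: _unbroadcast(g, a.shape)),
                  (b, lambda g: _unbroadcast(neg(g), b.shape))])


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return _make(a.data * b.data,
                 [(a, lambda g: _unbroadcast(mul(g, b), a.shape)),
                  (b, lambda g: _unbroadcast(mul(g, a), b.shape))])


def div(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return _make(a.data / b.data,
                 [(a, lambda g: _unbroadcast(div(g, b), a.shape)),
                  (b, lambda g: _unbroadcast(neg(div(mul(g, a), mul(b, b))), b.shape))])


def neg(a):
    a = as_tensor(a)
    return _make(-a.data, [(a, lambda g: neg(g))])


def power(a, c: float):
    a = as_tensor(a)
    c = float(c)
    return _make(a.data ** c,
                 [(a, lambda g: mul(g, mul(c, power(a, c - 1.0))))])


def exp(a):
    a = as_tensor(a)
    out = _make(np.exp(a.data), [(a, lambda g: mul(g, out))])
    return out


def log(a):
    a = as_tensor(a)
    return _make(np.log(a.data), [(a, lambda g: div(g, a))])


def sqrt(a):
    a = as_tensor(a)
    out = _make(np.sqrt(a.data), [(a, lambda g: div(g, mul(2.0, out)))])
    return out


def sigmoid(a):
    a = as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-a.data))
    out = _make(s, [(a, lambda g: mul(g, mul(out, sub(1.0, out))))])
    return out


def abs_(a):
    a = as_tensor(a)
    sign = np.sign(a.data)  # constant: |x| has zero curvature a.e.
    return _make(np.abs(a.data), [(a, lambda g: mul(g, Tensor(sign)))])


def clip(a, lo: float, hi: float):
    a = as_tensor(a)
    mask = ((a.data > lo) & (a.data < hi)).astype(DTYPE)
    return _make(np.clip(a.data, lo, hi), [(a, lambda g: mul(g, Tensor(mask)))])


def leaky_relu(a, slope: float = 0.2):
    a = as_tensor(a)
    mask = np.where(a.data > 0, 1.0, slope).astype(DTYPE)
    return _make(a.data * mask, [(a, lambda g: mul(g, Tensor(mask)))])


def swish(a):
    """x * sigmoid(x) — smooth, non-monotone activation.

    Fused: the derivative s*(1 + x*(1-s)) is stored as a constant array, so
    this op is exact to first order only.  It is used in the generators,
    which are never differentiated twice (the gradient penalty touches only
    the critics); critics use leaky_relu.
    """
    a = as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-a.data))
    d = s * (1.0 + a.data * (1.0 - s))
    return _make(a.data * s, [(a, lambda g: mul(g, Tensor(d)))])


# ---------------------------------------------------------------------------
# reductions and shape primitives
# ---------------------------------------------------------------------------

def sum_(a, axis=None, keepdims=False):
    a = as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        gd = g
        if not keepdims and axis is not None:
            ax = (axis,) if isinstance(axis, int) else tuple(axis)
            shp = list(g.shape)
            for i in sorted(a_ % a.ndim for a_ in ax):
                shp.insert(i, 1)
            gd = reshape(g, tuple(shp))
        elif not keepdims and axis is None:
            gd = reshape(g, (1,) * a.ndim)
        return broadcast_to(gd, a.shape)

    return _make(data, [(a, vjp)])


def mean(a, axis=None, keepdims=False):
    a = as_tensor(a)
    if axis is None:
        n = a.size
    else:
        ax = (axis,) if isinstance(axis, int) else tuple(axis)
        n = int(np.prod([a.shape[i] for i in ax]))
    return mul(sum_(a, axis=axis, keepdims=keepdims), 1.0 / n)


def broadcast_to(a, shape):
    a = as_tensor(a)
    if a.shape == tuple(shape):
        return a
    return _make(np.broadcast_to(a.data, shape).copy(),
                 [(a, lambda g: _unbroadcast(g, a.shape))])


def reshape(a, shape):
    a = as_tensor(a)
    if a.shape == tuple(shape):
        return a
    return _make(a.data.reshape(shape), [(a, lambda g: reshape(g, a.shape))])


def transpose(a, axes):
    a = as_tensor(a)
    inv = tuple(np.argsort(axes))
    return _make(a.data.transpose(axes), [(a, lambda g: transpose(g, inv))])


def concat(tensors, axis):
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    offs = np.cumsum([0] + [t.shape[axis] for t in tensors])

    def make_vjp(i):
        def vjp(g):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(int(offs[i]), int(offs[i + 1]))
            return getitem(g, tuple(idx))
        return vjp

    return _make(data, [(t, make_vjp(i)) for i, t in enumerate(tensors)])


def getitem(a, idx):
    a = as_tensor(a)
    return _make(a.data[idx], [(a, lambda g: scatter(g, a.shape, idx))])


def scatter(g, shape, idx):
    """Adjoint of basic slicing: place ``g`` into zeros of ``shape``."""
    g = as_tensor(g)
    data = np.zeros(shape, dtype=DTYPE)
    data[idx] = g.data
    return _make(data, [(g, lambda gg: getitem(gg, idx))])


def flip(a, axes):
    a = as_tensor(a)
    return _make(np.flip(a.data, axes).copy(), [(a, lambda g: flip(g, axes))])


def pad_zero(a, pad_width):
    a = as_tensor(a)
    data = np.pad(a.data, pad_width)

    def vjp(g):
        idx = tuple(slice(lo, lo + n) for (lo, _), n in zip(pad_width, a.shape))
        return getitem(g, idx)

    return _make(data, [(a, vjp)])


def matmul(a, b):
    """Strictly 2-D matrix product (batching is done by reshaping)."""
    a, b = as_tensor(a), as_tensor(b)
    return _make(a.data @ b.data,
                 [(a, lambda g: matmul(g, transpose(b, (1, 0)))),
                  (b, lambda g: matmul(transpose(a, (1, 0)), g))])


# ---------------------------------------------------------------------------
# convolution building blocks
# ---------------------------------------------------------------------------

_SCRATCH: dict = {}


def _scratch(shape):
    """Reusable transient buffer; avoids page-fault churn on big allocations.

    Safe because every scratch buffer is fully consumed (fed to a matmul or
    scatter) before the next request with the same shape can occur.
    """
    arr = _SCRATCH.get(shape)
    if arr is None:
        arr = np.empty(shape, dtype=DTYPE)
        _SCRATCH[shape] = arr
    return arr


def clear_scratch() -> None:
    _SCRATCH.clear()


def _out_hw(H, W, kh, kw, stride, pad):
    return ((H + 2 * pad - kh) // stride + 1,
            (W + 2 * pad - kw) // stride + 1)


def _im2col_np(x, kh, kw, stride, pad):
    """Patch matrix (B, C*kh*kw, oh*ow) in a pooled scratch buffer;
    zero-padding is folded into the gather bounds."""
    B, C, H, W = x.shape
    oh, ow = _out_hw(H, W, kh, kw, stride, pad)
    out = _scratch((B, C, kh, kw, oh, ow))
    _gather.im2col_fill(x, kh, kw, stride, stride, pad, out)
    return out.reshape(B, C * kh * kw, oh * ow), oh, ow


def dilate(x, s: int):
    """Insert ``s-1`` zeros between adjacent pixels (both spatial axes)."""
    x = as_tensor(x)
    if s == 1:
        return x
    B, C, H, W = x.shape
    data = np.zeros((B, C, (H - 1) * s + 1, (W - 1) * s + 1), dtype=DTYPE)
    data[:, :, ::s, ::s] = x.data
    return _make(data, [(x, lambda g: getitem(g, (slice(None), slice(None),
                                                  slice(None, None, s),
                                                  slice(None, None, s))))])


def _conv_fwd_np(x, w, stride, pad):
    B = x.shape[0]
    Cout, _, kh, kw = w.shape
    cols, oh, ow = _im2col_np(x, kh, kw, stride, pad)
    out = np.matmul(w.reshape(Cout, -1), cols)           # (B, Cout, L)
    return np.ascontiguousarray(out).reshape(B, Cout, oh, ow)


def _conv_dx_np(g, w, stride, pad, x_shape):
    B, C, H, W = x_shape
    Cout, _, kh, kw = w.shape
    oh, ow = g.shape[2], g.shape[3]
    K = C * kh * kw
    cols = _scratch((B, K, oh * ow))
    np.matmul(np.ascontiguousarray(w.reshape(Cout, -1).T),
              g.reshape(B, Cout, oh * ow), out=cols)
    dx = np.zeros(x_shape, dtype=DTYPE)
    _gather.col2im_add(cols.reshape(B, C, kh, kw, oh, ow),
                       stride, stride, pad, dx)
    return dx


def _conv_dw_np(x, g, stride, pad, w_shape):
    Cout, Cin, kh, kw = w_shape
    cols, oh, ow = _im2col_np(x, kh, kw, stride, pad)
    B = x.shape[0]
    g2 = g.reshape(B, Cout, oh * ow)
    dw = g2[0] @ cols[0].T
    for b in range(1, B):
        dw += g2[b] @ cols[b].T
    return dw.reshape(w_shape)


def conv2d(x, w, b=None, stride: int = 1, padding: int = 0):
    """Cross-correlation of (B,C,H,W) input with (Cout,Cin,kh,kw) weights,
    with an optional fused per-channel bias.

    A fused primitive: the im2col scratch buffer is freed right after the
    matmul instead of living in the graph.  Its input/weight vjps are
    primitives of the same family (the conv/dx/dw triality), so the
    operation is closed under repeated differentiation — required for the
    gradient penalty.
    """
    x, w = as_tensor(x), as_tensor(w)
    Cout, Cin, kh, kw = w.shape
    B, C, H, W = x.shape
    if C != Cin:
        raise ValueError(f"conv2d: input has {C} channels, weight expects {Cin}")
    if H + 2 * padding < kh or W + 2 * padding < kw:
        raise ValueError(f"conv2d: input {H}x{W} smaller than kernel {kh}x{kw}")
    x_shape, w_shape = x.shape, w.shape
    data = _conv_fwd_np(x.data, w.data, stride, padding)
    pairs = [(x, lambda g: conv2d_dx(g, w, stride, padding, x_shape)),
             (w, lambda g: conv2d_dw(x, g, stride, padding, w_shape))]
    if b is not None:
        b = as_tensor(b)
        data += b.data.reshape(1, Cout, 1, 1)
        pairs.append((b, lambda g: reshape(sum_(g, axis=(0, 2, 3)), b.shape)))
    return _make(data, pairs)


def conv2d_dx(g, w, stride, padding, x_shape):
    """Adjoint of conv2d with respect to its input (a transposed conv)."""
    g, w = as_tensor(g), as_tensor(w)
    data = _conv_dx_np(g.data, w.data, stride, padding, x_shape)
    return _make(data,
                 [(g, lambda u: conv2d(u, w, stride=stride, padding=padding)),
                  (w, lambda u: conv2d_dw(u, g, stride, padding, w.shape))])


def conv2d_dw(x, g, stride, padding, w_shape):
    """Adjoint of conv2d with respect to its weight."""
    x, g = as_tensor(x), as_tensor(g)
    x_shape = x.shape
    data = _conv_dw_np(x.data, g.data, stride, padding, w_shape)
    return _make(data,
                 [(x, lambda u: conv2d_dx(g, u, stride, padding, x_shape)),
                  (g, lambda u: conv2d(x, u, stride=stride, padding=padding))])


def conv_transpose2d(x, w, b=None, stride: int = 2, padding: int = 1):
    """Transposed convolution; weight layout (Cin, Cout, kh, kw).

    Implemented as zero-dilation followed by a stride-1 convolution with the
    spatially flipped, channel-swapped kernel, so the whole op stays inside
    the differentiable primitive set.  Output side = (H-1)*stride + k - 2*pad.
    """
    x, w = as_tensor(x), as_tensor(w)
    Cin, Cout, kh, kw = w.shape
    xd = dilate(x, stride)
    wf = transpose(flip(w, (2, 3)), (1, 0, 2, 3))
    return conv2d(xd, wf, b=b, stride=1, padding=kh - 1 - padding)


# ---------------------------------------------------------------------------
# backward pass
# ---------------------------------------------------------------------------

def _toposort(root: Tensor):
    order, seen = [], set()
    stack = [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for parent, _ in node._parents:
            if id(parent) not in seen:
                stack.append((parent, False))
    return order  # parents before children


def grad(output: Tensor, inputs, create_graph: bool = False):
    """Cotangents of a scalar ``output`` with respect to ``inputs``.

    With ``create_graph=True`` the returned tensors carry their own tape and
    can be differentiated again (needed for the gradient penalty).  Without
    it the pass is terminal: the graph's parent links are severed afterwards
    so the op/closure reference cycles (closures capture their own output
    node) free by reference counting instead of piling up for the cycle
    collector — essential for long training runs.
    """
    inputs = list(inputs)
    order = _toposort(output)
    cot: dict[int, Tensor] = {id(output): Tensor(np.ones_like(output.data))}
    keep = {id(t) for t in inputs}

    def run():
        for node in reversed(order):
            g = cot.get(id(node))
            if g is None:
                continue
            for parent, vjp in node._parents:
                pg = vjp(g)
                prev = cot.get(id(parent))
                cot[id(parent)] = pg if prev is None else add(prev, pg)
            if id(node) not in keep:
                del cot[id(node)]

    if create_graph:
        run()
    else:
        with no_grad():
            run()
        for node in order:
            node._parents = ()
    return [cot.get(id(t)) or Tensor(np.zeros_like(t.data)) for t in inputs]
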