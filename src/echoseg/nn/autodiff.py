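"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery to express and train the two-stream segmentation
network on a CPU: elementwise arithmetic, activations, reductions,
2-D convolution, nearest-neighbour upsampling, RoIAlign (bilinear region
cropping), gathering, reshaping and concatenation.  Gradients flow through
a dynamically recorded tape; ``Tensor.backward()`` runs the tape in reverse
topological order.

The default dtype is float32 for speed; set ``autodiff.DTYPE = np.float64``
(before building tensors) when doing numerical gradient checks.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph machinery -----------------------------------------------------
    def zero_grad(self):
        self.grad = None

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
        topo: list[Tensor] = []
        seen = set()
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(_as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(_as_tensor(other), mul(self, -1.0))

    def __truediv__(self, scalar):
        return mul(self, 1.0 / float(scalar))

    def __pow__(self, exponent):
        return power(self, exponent)

    def sum(self):
        return tsum(self)

    def mean(self):
        return tmean(self)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accum(t: Tensor, g: np.ndarray):
    if t.requires_grad:
        if t.grad is None:
            t.grad = np.zeros_like(t.data)
        t.grad += g


def _node(data, parents, backward) -> Tensor:
    req = any(p.requires_grad for p in parents)
    out = Tensor(data, requires_grad=req)
    if req:
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


# -- elementwise -------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data + b.data

    def backward(g):
        _accum(a, _unbroadcast(g, a.shape))
        _accum(b, _unbroadcast(g, b.shape))

    return _node(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data * b.data

    def backward(g):
        _accum(a, _unbroadcast(g * b.data, a.shape))
        _accum(b, _unbroadcast(g * a.data, b.shape))

    return _node(data, (a, b), backward)


def power(a, exponent: float) -> Tensor:
    a = _as_tensor(a)
    data = a.data ** exponent

    def backward(g):
        _accum(a, g * exponent * a.data ** (exponent - 1))

    return _node(data, (a,), backward)


def log(a) -> Tensor:
    a = _as_tensor(a)
    data = np.log(a.data)

    def backward(g):
        _accum(a, g / a.data)

    return _node(data, (a,), backward)


def tabs(a) -> Tensor:
    a = _as_tensor(a)
    data = np.abs(a.data)

    def backward(g):
        _accum(a, g * np.sign(a.data))

    return _node(data, (a,), backward)


def relu(a) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0
    data = a.data * mask

    def backward(g):
        _accum(a, g * mask)

    return _node(data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    from scipy.special import expit

    data = expit(a.data).astype(DTYPE)

    def backward(g):
        _accum(a, g * data * (1 - data))

    return _node(data, (a,), backward)


def clip(a, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes only through the unclamped region."""
    a = _as_tensor(a)
    data = np.clip(a.data, lo, hi)
    inside = (a.data > lo) & (a.data < hi)

    def backward(g):
        _accum(a, g * inside)

    return _node(data, (a,), backward)


def where_mask(cond: np.ndarray, a, b) -> Tensor:
    """Select a where cond else b; cond is a constant boolean array."""
    a, b = _as_tensor(a), _as_tensor(b)
    cond = np.asarray(cond, dtype=bool)
    data = np.where(cond, a.data, b.data)

    def backward(g):
        _accum(a, _unbroadcast(g * cond, a.shape))
        _accum(b, _unbroadcast(g * ~cond, b.shape))

    return _node(data, (a, b), backward)


# -- shape manipulation ------------------------------------------------------

def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    data = a.data.reshape(shape)

    def backward(g):
        _accum(a, g.reshape(a.shape))

    return _node(data, (a,), backward)


def transpose(a, axes) -> Tensor:
    a = _as_tensor(a)
    data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def backward(g):
        _accum(a, g.transpose(inv))

    return _node(data, (a,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, piece)

    return _node(data, tuple(tensors), backward)


def gather(a, indices: np.ndarray) -> Tensor:
    """Take elements of a flattened tensor at constant integer indices."""
    a = _as_tensor(a)
    indices = np.asarray(indices, dtype=np.intp)
    flat = a.data.reshape(-1)
    data = flat[indices]

    def backward(g):
        buf = np.zeros_like(flat)
        np.add.at(buf, indices, g.reshape(-1))
        _accum(a, buf.reshape(a.shape))

    return _node(data, (a,), backward)


def tile_batch(a, n: int) -> Tensor:
    """Repeat a (1, ...) tensor n times along the batch axis."""
    a = _as_tensor(a)
    if a.shape[0] != 1:
        raise ValueError("tile_batch expects batch size 1")
    data = np.repeat(a.data, n, axis=0)

    def backward(g):
        _accum(a, g.sum(axis=0, keepdims=True))

    return _node(data, (a,), backward)


# -- reductions --------------------------------------------------------------

def tsum(a) -> Tensor:
    a = _as_tensor(a)
    data = np.asarray(a.data.sum(), dtype=DTYPE)

    def backward(g):
        _accum(a, np.broadcast_to(g, a.shape).astype(DTYPE) * 1.0)

    return _node(data, (a,), backward)


def tmean(a) -> Tensor:
    a = _as_tensor(a)
    n = a.data.size
    data = np.asarray(a.data.mean(), dtype=DTYPE)

    def backward(g):
        _accum(a, np.broadcast_to(g / n, a.shape).astype(DTYPE) * 1.0)

    return _node(data, (a,), backward)


# -- spatial operators -------------------------------------------------------

def conv2d(x, w, b=None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation) over NCHW input.

    Implemented as a sum over kernel offsets of strided slices, which keeps
    both directions vectorized without materializing an im2col buffer.
    """
    x, w = _as_tensor(x), _as_tensor(w)
    xd, wd = x.data, w.data
    n, c, h, ww_ = xd.shape
    o, c2, kh, kw = wd.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input {c}, kernel {c2}")
    ho = (h + 2 * padding - kh) // stride + 1
    wo = (ww_ + 2 * padding - kw) // stride + 1
    xp = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    out = np.zeros((n, o, ho, wo), dtype=DTYPE)
    for i in range(kh):
        for j in range(kw):
            xs = xp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride]
            out += np.einsum("nchw,oc->nohw", xs, wd[:, :, i, j], optimize=True)
    if b is not None:
        b = _as_tensor(b)
        out += b.data.reshape(1, o, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if b is not None:
            _accum(b, g.sum(axis=(0, 2, 3)))
        gxp = np.zeros_like(xp) if x.requires_grad else None
        for i in range(kh):
            for j in range(kw):
                xs = xp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride]
                if w.requires_grad:
                    gw = np.einsum("nohw,nchw->oc", g, xs, optimize=True)
                    if w.grad is None:
                        w.grad = np.zeros_like(w.data)
                    w.grad[:, :, i, j] += gw
                if gxp is not None:
                    gxp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += \
                        np.einsum("nohw,oc->nchw", g, wd[:, :, i, j], optimize=True)
        if gxp is not None:
            if padding:
                gxp = gxp[:, :, padding:-padding or None, padding:-padding or None]
            _accum(x, gxp)

    return _node(out, parents, backward)


def upsample_nearest2x(a) -> Tensor:
    a = _as_tensor(a)
    data = a.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        n, c, h, w = a.shape
        _accum(a, g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    return _node(data, (a,), backward)


def roi_align(x, boxes: np.ndarray, batch_idx: np.ndarray,
              output_size: tuple[int, int], spatial_scale: float = 1.0) -> Tensor:
    """Bilinear region cropping without coordinate quantization.

    ``boxes`` are constant (R, 4) (x1, y1, x2, y2) in input-image
    coordinates; ``spatial_scale`` maps them onto the feature grid.  One
    sample per output bin, taken at the bin centre; feature pixel centres
    sit at integer coordinates + 0.5.
    """
    x = _as_tensor(x)
    boxes = np.asarray(boxes, dtype=float).reshape(-1, 4) * spatial_scale
    batch_idx = np.asarray(batch_idx, dtype=int).ravel()
    r = len(boxes)
    oh, ow = output_size
    n, c, h, w = x.shape
    if np.any(boxes[:, 2] <= boxes[:, 0]) or np.any(boxes[:, 3] <= boxes[:, 1]):
        raise ValueError("degenerate box in roi_align")

    bw = (boxes[:, 2] - boxes[:, 0]) / ow
    bh = (boxes[:, 3] - boxes[:, 1]) / oh
    sx = boxes[:, 0, None] + (np.arange(ow) + 0.5) * bw[:, None] - 0.5  # (R, ow)
    sy = boxes[:, 1, None] + (np.arange(oh) + 0.5) * bh[:, None] - 0.5  # (R, oh)

    x0 = np.floor(sx).astype(int)
    y0 = np.floor(sy).astype(int)
    fx = sx - x0
    fy = sy - y0
    x0c = np.clip(x0, 0, w - 1)
    x1c = np.clip(x0 + 1, 0, w - 1)
    y0c = np.clip(y0, 0, h - 1)
    y1c = np.clip(y0 + 1, 0, h - 1)

    out = np.zeros((r, c, oh, ow), dtype=DTYPE)
    corner_cache = []
    for ri in range(r):
        feat = x.data[batch_idx[ri]]  # (C, H, W)
        wy0, wy1 = (1 - fy[ri])[:, None], fy[ri][:, None]       # (oh, 1)
        wx0, wx1 = (1 - fx[ri])[None, :], fx[ri][None, :]       # (1, ow)
        yy0, yy1 = y0c[ri][:, None], y1c[ri][:, None]
        xx0, xx1 = x0c[ri][None, :], x1c[ri][None, :]
        out[ri] = (feat[:, yy0, xx0] * (wy0 * wx0)
                   + feat[:, yy0, xx1] * (wy0 * wx1)
                   + feat[:, yy1, xx0] * (wy1 * wx0)
                   + feat[:, yy1, xx1] * (wy1 * wx1))
        corner_cache.append((yy0, yy1, xx0, xx1, wy0, wy1, wx0, wx1))

    def backward(g):
        gx = np.zeros_like(x.data)
        for ri in range(r):
            yy0, yy1, xx0, xx1, wy0, wy1, wx0, wx1 = corner_cache[ri]
            gi = g[ri]  # (C, oh, ow)
            bi = batch_idx[ri]
            np.add.at(gx[bi], (slice(None), yy0, xx0), gi * (wy0 * wx0))
            np.add.at(gx[bi], (slice(None), yy0, xx1), gi * (wy0 * wx1))
            np.add.at(gx[bi], (slice(None), yy1, xx0), gi * (wy1 * wx0))
            np.add.at(gx[bi], (slice(None), yy1, xx1), gi * (wy1 * wx1))
        _accum(x, gx)

    return _node(out, (x,), backward)
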