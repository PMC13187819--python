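"""Minimal reverse-mode automatic differentiation over numpy arrays.

The end-to-end design loop differentiates a physical image-formation chain
(phase-mask heights -> complex pupil -> FFT -> intensity PSF -> convolution ->
sensor capture) followed by a convolutional restoration network.  This module
provides exactly the operator set that chain needs: elementwise arithmetic,
trigonometry, reductions, shape manipulation, 2-D convolution, pooling, and a
centered 2-D Fourier transform on complex tensors.

Complex tensors use the real inner product Re<u, v>; the stored cotangent of a
complex tensor is the adjoint under that product, so for real tensors it is the
ordinary gradient.  All adjoints are exercised against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "add", "sub", "mul", "div", "neg", "power", "exp", "log", "sqrt",
    "absolute", "relu", "leaky_relu", "cos", "sin", "clip",
    "tsum", "tmean", "reshape", "transpose", "pad2d", "crop2d", "concat",
    "matmul", "conv2d", "avg_pool2d", "adaptive_avg_pool2d", "region_upsample",
    "pixel_shuffle", "pixel_unshuffle", "stop_gradient", "flip2d",
    "make_complex", "cfft2", "cifft2", "cmul_const", "abs2",
    "grad_check",
]


class Tensor:
    """A node in the computation graph wrapping a numpy array."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad=False, _parents=(), name=None):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._parents = _parents
        self.name = name

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self):
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self):
        self.grad = None

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.array(g, copy=True)
        else:
            self.grad = self.grad + g

    def backward(self, grad=None):
        """Reverse-mode sweep from this (scalar or seeded) tensor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed requires a scalar output")
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
        for t in topo:
            t.grad = None
        self._accum(np.asarray(grad))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, p):
        return power(self, p)

    def __getitem__(self, idx):
        return _getitem(self, idx)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def tensor(data, requires_grad=False, name=None):
    return Tensor(np.asarray(data, dtype=float) if not np.iscomplexobj(data) else data,
                  requires_grad=requires_grad, name=name)


def _wrap(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _unbroadcast(g, shape):
    """Reduce a gradient back to the shape it was broadcast from."""
    if g.shape == tuple(shape):
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


def _node(data, parents, backward):
    req = any(p.requires_grad for p in parents)
    out = Tensor(data, requires_grad=req, _parents=tuple(p for p in parents if p.requires_grad))
    if req:
        out._backward = backward
    return out


# ----------------------------------------------------------------------
# elementwise arithmetic
# ----------------------------------------------------------------------

def add(a, b):
    a, b = _wrap(a), _wrap(b)

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.shape))

    return _node(a.data + b.data, (a, b), backward)


def sub(a, b):
    a, b = _wrap(a), _wrap(b)

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(-g, b.shape))

    return _node(a.data - b.data, (a, b), backward)


def mul(a, b):
    a, b = _wrap(a), _wrap(b)

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * np.conj(b.data) if np.iscomplexobj(b.data) else g * b.data, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * np.conj(a.data) if np.iscomplexobj(a.data) else g * a.data, b.shape))

    return _node(a.data * b.data, (a, b), backward)


def div(a, b):
    a, b = _wrap(a), _wrap(b)

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g / b.data, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.shape))

    return _node(a.data / b.data, (a, b), backward)


def neg(a):
    a = _wrap(a)

    def backward(g):
        a._accum(-g)

    return _node(-a.data, (a,), backward)


def power(a, p):
    a = _wrap(a)
    p = float(p)

    def backward(g):
        a._accum(g * p * a.data ** (p - 1))

    return _node(a.data ** p, (a,), backward)


def exp(a):
    a = _wrap(a)
    out_data = np.exp(a.data)

    def backward(g):
        a._accum(g * out_data)

    return _node(out_data, (a,), backward)


def log(a):
    a = _wrap(a)

    def backward(g):
        a._accum(g / a.data)

    return _node(np.log(a.data), (a,), backward)


def sqrt(a):
    a = _wrap(a)
    out_data = np.sqrt(a.data)

    def backward(g):
        a._accum(g * 0.5 / out_data)

    return _node(out_data, (a,), backward)


def absolute(a):
    a = _wrap(a)

    def backward(g):
        a._accum(g * np.sign(a.data))

    return _node(np.abs(a.data), (a,), backward)


def relu(a):
    a = _wrap(a)
    m = a.data > 0

    def backward(g):
        a._accum(g * m)

    return _node(a.data * m, (a,), backward)


def leaky_relu(a, alpha=0.1):
    a = _wrap(a)
    m = np.where(a.data > 0, 1.0, alpha)

    def backward(g):
        a._accum(g * m)

    return _node(a.data * m, (a,), backward)


def cos(a):
    a = _wrap(a)

    def backward(g):
        a._accum(-g * np.sin(a.data))

    return _node(np.cos(a.data), (a,), backward)


def sin(a):
    a = _wrap(a)

    def backward(g):
        a._accum(g * np.cos(a.data))

    return _node(np.sin(a.data), (a,), backward)


def clip(a, lo, hi):
    """Clamp with a straight-through (identity) gradient.

    Used for box constraints under projected gradient steps: a parameter
    pinned at a bound still receives the full gradient, so it can re-enter
    the feasible interior when the loss pulls it back.
    """
    a = _wrap(a)

    def backward(g):
        a._accum(g)

    return _node(np.clip(a.data, lo, hi), (a,), backward)


def stop_gradient(a):
    a = _wrap(a)
    return Tensor(a.data, requires_grad=False)


def flip2d(a):
    """Reverse both trailing axes (turns cross-correlation into convolution)."""
    a = _wrap(a)
    sl = tuple([slice(None)] * (a.ndim - 2) + [slice(None, None, -1)] * 2)

    def backward(g):
        a._accum(g[sl])

    return _node(a.data[sl], (a,), backward)


# ----------------------------------------------------------------------
# reductions and shape ops
# ----------------------------------------------------------------------

def tsum(a, axis=None, keepdims=False):
    a = _wrap(a)

    def backward(g):
        if axis is None:
            a._accum(np.broadcast_to(g, a.shape).copy() if np.ndim(g) else np.full(a.shape, g))
        else:
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.shape).copy())

    return _node(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)


def tmean(a, axis=None, keepdims=False):
    a = _wrap(a)
    n = a.data.size if axis is None else np.prod([a.shape[ax] for ax in np.atleast_1d(axis)])

    def backward(g):
        if axis is None:
            a._accum(np.full(a.shape, np.asarray(g) / n))
        else:
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg / n, a.shape).copy())

    return _node(a.data.mean(axis=axis, keepdims=keepdims), (a,), backward)


def reshape(a, shape):
    a = _wrap(a)
    old = a.shape

    def backward(g):
        a._accum(g.reshape(old))

    return _node(a.data.reshape(shape), (a,), backward)


def transpose(a, axes):
    a = _wrap(a)
    inv = np.argsort(axes)

    def backward(g):
        a._accum(g.transpose(inv))

    return _node(a.data.transpose(axes), (a,), backward)


def _getitem(a, idx):
    a = _wrap(a)

    def backward(g):
        full = np.zeros(a.shape, dtype=g.dtype)
        np.add.at(full, idx, g)
        a._accum(full)

    return _node(a.data[idx], (a,), backward)


def pad2d(a, pad):
    """Zero-pad the two trailing axes by ``pad`` (int or (ph, pw))."""
    a = _wrap(a)
    ph, pw = (pad, pad) if np.isscalar(pad) else pad
    width = [(0, 0)] * (a.ndim - 2) + [(ph, ph), (pw, pw)]

    def backward(g):
        sl = tuple([slice(None)] * (a.ndim - 2) + [slice(ph, g.shape[-2] - ph), slice(pw, g.shape[-1] - pw)])
        a._accum(g[sl])

    return _node(np.pad(a.data, width), (a,), backward)


def crop2d(a, top, left, height, width):
    a = _wrap(a)
    sl = tuple([slice(None)] * (a.ndim - 2) + [slice(top, top + height), slice(left, left + width)])

    def backward(g):
        full = np.zeros(a.shape, dtype=g.dtype)
        full[sl] = g
        a._accum(full)

    return _node(a.data[sl], (a,), backward)


def concat(tensors, axis):
    tensors = [_wrap(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, o, s in zip(tensors, offsets[:-1], sizes):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(o, o + s)
                t._accum(g[tuple(sl)])

    return _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward)


def matmul(a, b):
    a, b = _wrap(a), _wrap(b)

    def backward(g):
        if a.requires_grad:
            a._accum(g @ np.swapaxes(b.data, -1, -2))
        if b.requires_grad:
            b._accum(np.swapaxes(a.data, -1, -2) @ g)

    return _node(a.data @ b.data, (a, b), backward)


# ----------------------------------------------------------------------
# convolution and pooling (NCHW)
# ----------------------------------------------------------------------

def _im2col(x, kh, kw, stride):
    n, c, h, w = x.shape
    oh = (h - kh) // stride + 1
    ow = (w - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]            # (n, c, oh, ow, kh, kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh * ow, c * kh * kw)
    return cols, oh, ow


def _col2im(cols, x_shape, kh, kw, stride, oh, ow):
    n, c, h, w = x_shape
    dx = np.zeros(x_shape, dtype=cols.dtype)
    cols = cols.reshape(n, oh, ow, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += cols[:, :, :, :, i, j]
    return dx


def conv2d(x, weight, bias=None, stride=1, padding=0):
    """2-D cross-correlation, NCHW input, OIHW weight."""
    x, weight = _wrap(x), _wrap(weight)
    if bias is not None:
        bias = _wrap(bias)
    xp = x if padding == 0 else pad2d(x, padding)
    n, c, h, w = xp.shape
    oc, ic, kh, kw = weight.shape
    if ic != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {ic}")
    cols, oh, ow = _im2col(xp.data, kh, kw, stride)
    wmat = weight.data.reshape(oc, -1)
    out_data = (cols @ wmat.T).transpose(0, 2, 1).reshape(n, oc, oh, ow)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, oc, 1, 1)

    parents = (xp, weight) + ((bias,) if bias is not None else ())

    def backward(g):
        gmat = g.reshape(n, oc, oh * ow).transpose(0, 2, 1)       # (n, ohw, oc)
        if weight.requires_grad:
            dw = np.einsum("npo,npk->ok", gmat, cols).reshape(weight.shape)
            weight._accum(dw)
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if xp.requires_grad:
            dcols = gmat @ wmat                                    # (n, ohw, c*kh*kw)
            xp._accum(_col2im(dcols, xp.shape, kh, kw, stride, oh, ow))

    return _node(out_data, parents, backward)


def avg_pool2d(x, k):
    x = _wrap(x)
    n, c, h, w = x.shape
    if h % k or w % k:
        raise ValueError("avg_pool2d requires divisible spatial dims")
    out_data = x.data.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))

    def backward(g):
        gg = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
        x._accum(gg)

    return _node(out_data, (x,), backward)


def _pool_regions(size, bins):
    edges = [(int(np.floor(i * size / bins)), int(np.floor((i + 1) * size / bins))) for i in range(bins)]
    return edges


def adaptive_avg_pool2d(x, bins):
    """Average pooling to a bins x bins output with uneven regions (pyramid pooling).

    ``bins`` is an int or an (h_bins, w_bins) pair.
    """
    x = _wrap(x)
    n, c, h, w = x.shape
    bh, bw = (bins, bins) if np.isscalar(bins) else bins
    rh, rw = _pool_regions(h, bh), _pool_regions(w, bw)
    out_data = np.empty((n, c, bh, bw), dtype=x.data.dtype)
    for i, (h0, h1) in enumerate(rh):
        for j, (w0, w1) in enumerate(rw):
            out_data[:, :, i, j] = x.data[:, :, h0:h1, w0:w1].mean(axis=(2, 3))

    def backward(g):
        dx = np.zeros(x.shape, dtype=g.dtype)
        for i, (h0, h1) in enumerate(rh):
            for j, (w0, w1) in enumerate(rw):
                area = (h1 - h0) * (w1 - w0)
                dx[:, :, h0:h1, w0:w1] += g[:, :, i:i + 1, j:j + 1] / area
        x._accum(dx)

    return _node(out_data, (x,), backward)


def region_upsample(x, out_hw):
    """Broadcast each input cell over its adaptive-pool region (inverse layout of
    adaptive_avg_pool2d); used to lift pyramid-pooled context back to full size."""
    x = _wrap(x)
    n, c, bh, bw = x.shape
    H, W = out_hw
    rh, rw = _pool_regions(H, bh), _pool_regions(W, bw)
    out_data = np.empty((n, c, H, W), dtype=x.data.dtype)
    for i, (h0, h1) in enumerate(rh):
        for j, (w0, w1) in enumerate(rw):
            out_data[:, :, h0:h1, w0:w1] = x.data[:, :, i:i + 1, j:j + 1]

    def backward(g):
        dx = np.empty(x.shape, dtype=g.dtype)
        for i, (h0, h1) in enumerate(rh):
            for j, (w0, w1) in enumerate(rw):
                dx[:, :, i, j] = g[:, :, h0:h1, w0:w1].sum(axis=(2, 3))
        x._accum(dx)

    return _node(out_data, (x,), backward)


def pixel_shuffle(x, r):
    """(N, C*r^2, H, W) -> (N, C, H*r, W*r) channel-to-space rearrangement."""
    x = _wrap(x)
    n, cr2, h, w = x.shape
    c = cr2 // (r * r)
    if c * r * r != cr2:
        raise ValueError("channel count not divisible by r^2")
    y = reshape(x, (n, c, r, r, h, w))
    y = transpose(y, (0, 1, 4, 2, 5, 3))
    return reshape(y, (n, c, h * r, w * r))


def pixel_unshuffle(x, r):
    x = _wrap(x)
    n, c, hr, wr = x.shape
    h, w = hr // r, wr // r
    y = reshape(x, (n, c, h, r, w, r))
    y = transpose(y, (0, 1, 3, 5, 2, 4))
    return reshape(y, (n, c * r * r, h, w))


# ----------------------------------------------------------------------
# complex ops for the optical chain
# ----------------------------------------------------------------------

def make_complex(re, im):
    re, im = _wrap(re), _wrap(im)

    def backward(g):
        if re.requires_grad:
            re._accum(np.real(g))
        if im.requires_grad:
            im._accum(np.imag(g))

    return _node(re.data + 1j * im.data, (re, im), backward)


def _centered_fft2(z):
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(z, axes=(-2, -1)), norm="ortho"),
                           axes=(-2, -1))


def _centered_ifft2(z):
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(z, axes=(-2, -1)), norm="ortho"),
                           axes=(-2, -1))


def cfft2(z):
    """Centered, orthonormal 2-D DFT on a complex tensor (zero frequency at grid center)."""
    z = _wrap(z)

    def backward(g):
        z._accum(_centered_ifft2(g))

    return _node(_centered_fft2(z.data), (z,), backward)


def cifft2(z):
    z = _wrap(z)

    def backward(g):
        z._accum(_centered_fft2(g))

    return _node(_centered_ifft2(z.data), (z,), backward)


def cmul_const(z, c):
    """Multiply a complex tensor by a constant complex array."""
    z = _wrap(z)
    c = np.asarray(c)

    def backward(g):
        z._accum(g * np.conj(c))

    return _node(z.data * c, (z,), backward)


def abs2(z):
    """Squared modulus of a complex tensor; output is real."""
    z = _wrap(z)

    def backward(g):
        z._accum(2.0 * g * z.data)

    return _node((z.data * np.conj(z.data)).real, (z,), backward)


# ----------------------------------------------------------------------
# finite-difference checker
# ----------------------------------------------------------------------

def grad_check(fn, params, eps=1e-6):
    """Max relative error between reverse-mode and central-difference gradients.

    ``fn(*params) -> scalar Tensor``; ``params`` are real Tensors with
    requires_grad=True.
    """
    out = fn(*params)
    out.backward()
    analytic = [p.grad.copy() for p in params]
    worst = 0.0
    for p, ga in zip(params, analytic):
        flat = p.data.ravel()
        gnum = np.zeros_like(flat)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            up = fn(*params).data.item()
            flat[i] = orig - eps
            dn = fn(*params).data.item()
            flat[i] = orig
            gnum[i] = (up - dn) / (2 * eps)
        denom = max(np.abs(ga).max(), np.abs(gnum).max(), 1e-12)
        worst = max(worst, np.abs(ga.ravel() - gnum).max() / denom)
    return worst
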