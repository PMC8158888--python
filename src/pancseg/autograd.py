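"""A minimal reverse-mode automatic-differentiation engine on numpy arrays.

This is the numerical substrate for the segmentation network: tensors that
record the operations applied to them and replay the chain rule backwards.
The op set is exactly what an encoder-decoder CNN with attention needs —
elementwise arithmetic with broadcasting, ReLU/sigmoid, reductions, channel
concatenation, 2D/3D convolution (stride 1, explicit padding), 2x2 max
pooling, and factor-2 bilinear upsampling — plus an Adam optimiser.

Convolutions are evaluated as im2col + BLAS matmul, which keeps the Python
overhead negligible at the feature-map sizes this package trains at.  All
gradients are checked against central finite differences in the test suite.

Layout conventions: 2D feature maps are ``(N, C, H, W)``, volumetric maps
``(N, C, D, H, W)``.
"""

from __future__ import annotations

from contextlib import contextmanager
from typing import Callable, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import expit

__all__ = [
    "Tensor",
    "no_grad",
    "add",
    "sub",
    "mul",
    "div",
    "pow_",
    "relu",
    "sigmoid",
    "tsum",
    "amax",
    "concat",
    "reshape",
    "conv2d",
    "conv3d",
    "maxpool2x2",
    "upsample2x_bilinear",
    "instance_norm",
    "Adam",
]

_grad_enabled = True


@contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: Tuple["Tensor", ...] = (),
        backward: Optional[Callable[[np.ndarray], None]] = None,
    ):
        self.data = np.asarray(data)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # -- graph traversal ---------------------------------------------------
    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: List[Tensor] = []
        seen = set()
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
        self.grad = np.asarray(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- conveniences ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        return tsum(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def item(self) -> float:
        return float(self.data)

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

    def __pow__(self, p):
        return pow_(self, p)

    def __neg__(self):
        return mul(self, -1.0)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _accum(t: Tensor, g: np.ndarray) -> None:
    if t.requires_grad or t._parents:
        t.grad = g if t.grad is None else t.grad + g


def _make(data: np.ndarray, parents: Tuple[Tensor, ...], backward) -> Tensor:
    if _grad_enabled and any(p.requires_grad or p._parents for p in parents):
        return Tensor(data, requires_grad=False, parents=parents, backward=backward)
    return Tensor(data)


def _unbroadcast(g: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum a gradient back down to the shape it was broadcast from."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# -- elementwise arithmetic ------------------------------------------------
# Python-number operands take a scalar path that preserves the array dtype
# (wrapping them as 0-dim float64 arrays would silently promote float32
# graphs to double precision).

def _scalar_op(a: Tensor, s: float, fwd, dfda) -> Tensor:
    out_data = fwd(a.data, s)

    def bwd(g):
        _accum(a, dfda(g, a.data, s))

    return _make(out_data, (a,), bwd)


def add(a, b) -> Tensor:
    if isinstance(a, Tensor) and isinstance(b, (int, float)):
        return _scalar_op(a, b, lambda x, s: x + s, lambda g, x, s: g)
    if isinstance(b, Tensor) and isinstance(a, (int, float)):
        return add(b, a)
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def bwd(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), bwd)


def sub(a, b) -> Tensor:
    if isinstance(a, Tensor) and isinstance(b, (int, float)):
        return _scalar_op(a, b, lambda x, s: x - s, lambda g, x, s: g)
    if isinstance(b, Tensor) and isinstance(a, (int, float)):
        return _scalar_op(b, a, lambda x, s: s - x, lambda g, x, s: -g)
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data - b.data

    def bwd(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(-g, b.data.shape))

    return _make(out_data, (a, b), bwd)


def mul(a, b) -> Tensor:
    if isinstance(a, Tensor) and isinstance(b, (int, float)):
        return _scalar_op(a, b, lambda x, s: x * s, lambda g, x, s: g * s)
    if isinstance(b, Tensor) and isinstance(a, (int, float)):
        return mul(b, a)
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def bwd(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), bwd)


def div(a, b) -> Tensor:
    if isinstance(a, Tensor) and isinstance(b, (int, float)):
        return _scalar_op(a, b, lambda x, s: x / s, lambda g, x, s: g / s)
    if isinstance(b, Tensor) and isinstance(a, (int, float)):
        return _scalar_op(b, a, lambda x, s: s / x, lambda g, x, s: -g * s / (x * x))
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data / b.data

    def bwd(g):
        _accum(a, _unbroadcast(g / b.data, a.data.shape))
        _accum(b, _unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

    return _make(out_data, (a, b), bwd)


def pow_(a, p: float) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data ** p

    def bwd(g):
        _accum(a, g * p * a.data ** (p - 1.0))

    return _make(out_data, (a,), bwd)


def relu(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0
    out_data = np.where(mask, a.data, 0.0)

    def bwd(g):
        _accum(a, g * mask)

    return _make(out_data, (a,), bwd)


def sigmoid(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    s = expit(a.data)

    def bwd(g):
        _accum(a, g * s * (1.0 - s))

    return _make(s, (a,), bwd)


# -- reductions ------------------------------------------------------------

def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def bwd(g):
        if axis is None:
            _accum(a, np.broadcast_to(g, a.data.shape).copy())
            return
        gg = g
        if not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            for ax in sorted(a_ % a.data.ndim for a_ in axes):
                gg = np.expand_dims(gg, ax)
        _accum(a, np.broadcast_to(gg, a.data.shape).copy())

    return _make(out_data, (a,), bwd)


def amax(a: Tensor, axis: Tuple[int, ...], keepdims: bool = False) -> Tensor:
    """Maximum over ``axis``; ties share the gradient equally."""
    a = _as_tensor(a)
    out_keep = a.data.max(axis=axis, keepdims=True)
    out_data = out_keep if keepdims else np.squeeze(out_keep, axis=axis)

    def bwd(g):
        gg = g if keepdims else np.reshape(g, out_keep.shape)
        mask = (a.data == out_keep).astype(a.data.dtype)
        counts = mask.sum(axis=axis, keepdims=True)
        _accum(a, mask * (gg / counts))

    return _make(out_data, (a,), bwd)


# -- shape ops -------------------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accum(t, g[tuple(sl)])

    return _make(out_data, tuple(tensors), bwd)


def reshape(a: Tensor, shape: Tuple[int, ...]) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data.reshape(shape)

    def bwd(g):
        _accum(a, g.reshape(a.data.shape))

    return _make(out_data, (a,), bwd)


# -- convolution -----------------------------------------------------------

def _shift_corr(xp: np.ndarray, w: np.ndarray, sp: Tuple[int, ...]) -> np.ndarray:
    """Valid cross-correlation of a padded input with kernel w via
    shift-and-matmul: one channel matmul per kernel offset.

    xp: (N, C, *padded_spatial); w: (O, C, *k); sp: output spatial shape.
    Faster than im2col at these sizes — the per-offset slices copy almost
    contiguously instead of gathering a 6D strided view.
    """
    n, c = xp.shape[:2]
    o = w.shape[0]
    ks = w.shape[2:]
    p = int(np.prod(sp))
    wm = w.reshape(o, c, -1)
    out = None
    for k in range(wm.shape[2]):
        idx = np.unravel_index(k, ks)
        sl = (slice(None), slice(None)) + tuple(
            slice(i, i + s) for i, s in zip(idx, sp)
        )
        xs = np.ascontiguousarray(xp[sl]).reshape(n, c, p)
        r = wm[:, :, k] @ xs
        out = r if out is None else out + r
    return out.reshape((n, o) + tuple(sp))


def _shift_dw(xp: np.ndarray, g: np.ndarray, ks: Tuple[int, ...]) -> np.ndarray:
    """Weight gradient of _shift_corr: per-offset tensordot of the output
    gradient with the shifted input."""
    n, c = xp.shape[:2]
    o = g.shape[1]
    sp = g.shape[2:]
    p = int(np.prod(sp))
    gm = g.reshape(n, o, p)
    nk = int(np.prod(ks))
    dw = np.empty((o, c, nk), dtype=xp.dtype)
    for k in range(nk):
        idx = np.unravel_index(k, ks)
        sl = (slice(None), slice(None)) + tuple(
            slice(i, i + s) for i, s in zip(idx, sp)
        )
        xs = np.ascontiguousarray(xp[sl]).reshape(n, c, p)
        dw[:, :, k] = np.tensordot(gm, xs, axes=([0, 2], [0, 2]))
    return dw.reshape((o, c) + tuple(ks))


def _conv1x1_2d(x: Tensor, w: Tensor, b: Optional[Tensor]) -> Tensor:
    """Fast path for pointwise convolution: a channel matmul."""
    n, cin, h, wd = x.data.shape
    cout = w.data.shape[0]
    wm = w.data.reshape(cout, cin)
    out = np.einsum("oc,nchw->nohw", wm, x.data, optimize=True)
    if b is not None:
        out += b.data[None, :, None, None]

    def bwd(g):
        if w.requires_grad or w._parents:
            _accum(w, np.einsum("nohw,nchw->oc", g, x.data, optimize=True).reshape(w.data.shape))
        if b is not None and (b.requires_grad or b._parents):
            _accum(b, g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            _accum(x, np.einsum("oc,nohw->nchw", wm, g, optimize=True))

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, bwd)


def conv2d(x: Tensor, w: Tensor, b: Optional[Tensor] = None, pad: int = 0) -> Tensor:
    """2D convolution (cross-correlation), stride 1, symmetric zero padding.

    x: (N, Cin, H, W); w: (Cout, Cin, kh, kw); b: (Cout,) or None.
    The input gradient is computed as a full correlation of the output
    gradient with the flipped kernel (im2col + matmul, no scatter loops).
    """
    x, w = _as_tensor(x), _as_tensor(w)
    if b is not None:
        b = _as_tensor(b)
    n, cin, h, wd = x.data.shape
    cout, cin_w, kh, kw = w.data.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input {cin} vs weight {cin_w}")
    if kh == 1 and kw == 1 and pad == 0:
        return _conv1x1_2d(x, w, b)
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    ho, wo = xp.shape[2] - kh + 1, xp.shape[3] - kw + 1
    out_data = _shift_corr(xp, w.data, (ho, wo))
    if b is not None:
        out_data += b.data[None, :, None, None]

    def bwd(g):
        if w.requires_grad or w._parents:
            _accum(w, _shift_dw(xp, g, (kh, kw)))
        if b is not None and (b.requires_grad or b._parents):
            _accum(b, g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            ph, pw = kh - 1 - pad, kw - 1 - pad
            gp = np.pad(g, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
            wf = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (Cin, Cout, kh, kw)
            _accum(x, _shift_corr(gp, np.ascontiguousarray(wf), (h, wd)))

    parents = (x, w) if b is None else (x, w, b)
    return _make(out_data, parents, bwd)


def _conv1x1_3d(x: Tensor, w: Tensor, b: Optional[Tensor]) -> Tensor:
    cout, cin = w.data.shape[:2]
    wm = w.data.reshape(cout, cin)
    out = np.einsum("oc,ncdhw->nodhw", wm, x.data, optimize=True)
    if b is not None:
        out += b.data[None, :, None, None, None]

    def bwd(g):
        if w.requires_grad or w._parents:
            _accum(w, np.einsum("nodhw,ncdhw->oc", g, x.data, optimize=True).reshape(w.data.shape))
        if b is not None and (b.requires_grad or b._parents):
            _accum(b, g.sum(axis=(0, 2, 3, 4)))
        if x.requires_grad or x._parents:
            _accum(x, np.einsum("oc,nodhw->ncdhw", wm, g, optimize=True))

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, bwd)


def conv3d(x: Tensor, w: Tensor, b: Optional[Tensor] = None, pad: int = 0) -> Tensor:
    """3D convolution, stride 1, symmetric zero padding on (D, H, W).

    x: (N, Cin, D, H, W); w: (Cout, Cin, kd, kh, kw).
    """
    x, w = _as_tensor(x), _as_tensor(w)
    if b is not None:
        b = _as_tensor(b)
    n, cin, d, h, wd = x.data.shape
    cout, cin_w, kd, kh, kw = w.data.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input {cin} vs weight {cin_w}")
    if kd == kh == kw == 1 and pad == 0:
        return _conv1x1_3d(x, w, b)
    p = ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad))
    xp = np.pad(x.data, p) if pad else x.data
    do, ho, wo = (xp.shape[2] - kd + 1, xp.shape[3] - kh + 1, xp.shape[4] - kw + 1)
    out_data = _shift_corr(xp, w.data, (do, ho, wo))
    if b is not None:
        out_data += b.data[None, :, None, None, None]

    def bwd(g):
        if w.requires_grad or w._parents:
            _accum(w, _shift_dw(xp, g, (kd, kh, kw)))
        if b is not None and (b.requires_grad or b._parents):
            _accum(b, g.sum(axis=(0, 2, 3, 4)))
        if x.requires_grad or x._parents:
            pp = (kd - 1 - pad, kh - 1 - pad, kw - 1 - pad)
            gp = np.pad(g, ((0, 0), (0, 0)) + tuple((q, q) for q in pp))
            wf = w.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
            _accum(x, _shift_corr(gp, np.ascontiguousarray(wf), (d, h, wd)))

    parents = (x, w) if b is None else (x, w, b)
    return _make(out_data, parents, bwd)


# -- pooling / resampling --------------------------------------------------

def maxpool2x2(x: Tensor) -> Tensor:
    """2x2/stride-2 max pooling over the last two axes (any leading dims)."""
    x = _as_tensor(x)
    shp = x.data.shape
    h, w = shp[-2], shp[-1]
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2x2 requires even spatial dims, got {(h, w)}")
    lead = shp[:-2]
    xr = x.data.reshape(lead + (h // 2, 2, w // 2, 2))
    xm = np.moveaxis(xr, -3, -2)  # (..., h2, w2, 2, 2)
    xf = xm.reshape(lead + (h // 2, w // 2, 4))
    idx = xf.argmax(axis=-1)
    out_data = np.take_along_axis(xf, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        gf = np.zeros(lead + (h // 2, w // 2, 4), dtype=g.dtype)
        np.put_along_axis(gf, idx[..., None], g[..., None], axis=-1)
        gm = gf.reshape(lead + (h // 2, w // 2, 2, 2))
        gr = np.moveaxis(gm, -2, -3)
        _accum(x, gr.reshape(shp))

    return _make(out_data, (x,), bwd)


def _up2_coeffs(n: int):
    """Indices/weights for factor-2 linear interpolation (align_corners=False)."""
    pos = (np.arange(2 * n) + 0.5) / 2.0 - 0.5
    i0 = np.floor(pos).astype(np.int64)
    frac = pos - i0
    i0c = np.clip(i0, 0, n - 1)
    i1c = np.clip(i0 + 1, 0, n - 1)
    return i0c, i1c, frac


def _up2_adjoint_axis(g: np.ndarray, axis: int) -> np.ndarray:
    """Adjoint of factor-2 linear upsampling along ``axis``.

    With the fixed interpolation pattern the transpose is a strided
    4-tap correlation [0.25, 0.75, 0.75, 0.25] plus two edge terms from
    index clamping — fully vectorised, no scatter.
    """
    g = np.moveaxis(g, axis, -1)
    m = g.shape[-1]  # = 2n
    n = m // 2
    pad = [(0, 0)] * (g.ndim - 1) + [(1, 2)]
    gp = np.pad(g, pad)
    out = (
        0.25 * gp[..., 0 : 2 * n : 2]
        + 0.75 * gp[..., 1 : 2 * n + 1 : 2]
        + 0.75 * gp[..., 2 : 2 * n + 2 : 2]
        + 0.25 * gp[..., 3 : 2 * n + 3 : 2]
    )
    out[..., 0] += 0.25 * g[..., 0]
    out[..., -1] += 0.25 * g[..., -1]
    return np.moveaxis(out, -1, axis)


def upsample2x_bilinear(x: Tensor) -> Tensor:
    """Bilinear x2 upsampling over the last two axes of a 4D tensor
    (align_corners=False convention; edges clamp)."""
    x = _as_tensor(x)
    dt = x.data.dtype if x.data.dtype.kind == "f" else np.float64
    n, c, h, w = x.data.shape
    i0h, i1h, fh = _up2_coeffs(h)
    i0w, i1w, fw = _up2_coeffs(w)
    fh_col = fh.astype(dt)[:, None]
    fw_row = fw.astype(dt)
    xh = x.data[:, :, i0h, :] * (1 - fh_col) + x.data[:, :, i1h, :] * fh_col
    out_data = xh[:, :, :, i0w] * (1 - fw_row) + xh[:, :, :, i1w] * fw_row

    def bwd(g):
        _accum(x, _up2_adjoint_axis(_up2_adjoint_axis(g, -1), -2))

    return _make(out_data, (x,), bwd)


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel normalisation over all spatial axes.

    x: (N, C, *spatial); gamma, beta: (C,).  Fused analytic backward.
    """
    x, gamma, beta = _as_tensor(x), _as_tensor(gamma), _as_tensor(beta)
    nd = x.data.ndim
    sp = tuple(range(2, nd))
    pshape = (1, x.data.shape[1]) + (1,) * (nd - 2)
    mu = x.data.mean(axis=sp, keepdims=True)
    xc = x.data - mu
    var = np.mean(xc * xc, axis=sp, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xn = xc * inv
    out_data = xn * gamma.data.reshape(pshape) + beta.data.reshape(pshape)

    def bwd(g):
        if beta.requires_grad or beta._parents:
            _accum(beta, g.sum(axis=(0,) + sp))
        if gamma.requires_grad or gamma._parents:
            _accum(gamma, (g * xn).sum(axis=(0,) + sp))
        if x.requires_grad or x._parents:
            dxn = g * gamma.data.reshape(pshape)
            m1 = dxn.mean(axis=sp, keepdims=True)
            m2 = (dxn * xn).mean(axis=sp, keepdims=True)
            _accum(x, inv * (dxn - m1 - xn * m2))

    return _make(out_data, (x, gamma, beta), bwd)


# -- optimiser -------------------------------------------------------------

class Adam:
    """Adam with bias correction (Kingma & Ba defaults for betas/eps)."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-3,
        betas: Tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * (g * g)
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
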