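"""Compact reverse-mode automatic differentiation on numpy arrays.

Provides exactly the operations the harmonization networks need: 2D
convolution (im2col), pixel shuffle/unshuffle, leaky ReLU, sigmoid,
elementwise arithmetic with broadcasting, channel/spatial means, concat,
and L1/L2 reductions, plus an Adam optimizer.  Tensors carry float64 data;
gradients are accumulated by a topological backward pass.
"""

from __future__ import annotations

from typing import Callable, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._parents: Tuple["Tensor", ...] = ()
        self._backward: Optional[Callable[[np.ndarray], Tuple[np.ndarray, ...]]] = None

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- graph machinery ----------------------------------------------------

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: List[Tensor] = []
        seen = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad:
                t.grad = g if t.grad is None else t.grad + g
            if t._backward is None:
                continue
            for p, pg in zip(t._parents, t._backward(g)):
                if pg is None:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg

    # -- operator sugar -----------------------------------------------------

    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __sub__(self, other):
        return add(self, mul_scalar(_wrap(other), -1.0))

    def __rsub__(self, other):
        return add(_wrap(other), mul_scalar(self, -1.0))

    def __mul__(self, other):
        if np.isscalar(other):
            return mul_scalar(self, float(other))
        return mul(self, other)

    __rmul__ = __mul__


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _op(data: np.ndarray, parents: Tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._backward is not None for p in parents):
        out._parents = parents
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise ops
# ---------------------------------------------------------------------------


def add(a: Tensor, b: Tensor) -> Tensor:
    return _op(
        a.data + b.data,
        (a, b),
        lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)),
    )


def mul(a: Tensor, b: Tensor) -> Tensor:
    return _op(
        a.data * b.data,
        (a, b),
        lambda g: (
            _unbroadcast(g * b.data, a.shape),
            _unbroadcast(g * a.data, b.shape),
        ),
    )


def mul_scalar(a: Tensor, s: float) -> Tensor:
    return _op(a.data * s, (a,), lambda g: (g * s,))


def add_scalar(a: Tensor, s: float) -> Tensor:
    return _op(a.data + s, (a,), lambda g: (g,))


def square(a: Tensor) -> Tensor:
    return _op(a.data**2, (a,), lambda g: (2.0 * a.data * g,))


def abs_(a: Tensor) -> Tensor:
    return _op(np.abs(a.data), (a,), lambda g: (np.sign(a.data) * g,))


def leaky_relu(a: Tensor, slope: float = 0.2) -> Tensor:
    m = np.where(a.data > 0, 1.0, slope)
    return _op(a.data * m, (a,), lambda g: (g * m,))


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60, 60)))
    return _op(s, (a,), lambda g: (g * s * (1 - s),))


def mean(a: Tensor) -> Tensor:
    n = a.data.size
    return _op(
        np.asarray(a.data.mean()), (a,), lambda g: (np.full(a.shape, g / n),)
    )


def mean_hw(a: Tensor) -> Tensor:
    """Mean over the spatial axes of an (N, C, H, W) tensor, keeping dims."""
    n_, c, h, w = a.shape
    return _op(
        a.data.mean(axis=(2, 3), keepdims=True),
        (a,),
        lambda g: (np.broadcast_to(g / (h * w), a.shape).copy(),),
    )


def mean_channel(a: Tensor) -> Tensor:
    """Mean over the channel axis of (N, C, H, W), keeping dims."""
    c = a.shape[1]
    return _op(
        a.data.mean(axis=1, keepdims=True),
        (a,),
        lambda g: (np.broadcast_to(g / c, a.shape).copy(),),
    )


def concat_channels(tensors: Sequence[Tensor]) -> Tensor:
    sizes = [t.shape[1] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        return tuple(np.split(g, splits, axis=1))

    return _op(np.concatenate([t.data for t in tensors], axis=1), tuple(tensors), bwd)


# ---------------------------------------------------------------------------
# pixel shuffle / unshuffle (lossless space <-> depth permutations)
# ---------------------------------------------------------------------------


def pixel_unshuffle_array(x: np.ndarray, r: int) -> np.ndarray:
    n, c, h, w = x.shape
    if h % r or w % r:
        raise ValueError(f"spatial dims {(h, w)} not divisible by factor {r}")
    y = x.reshape(n, c, h // r, r, w // r, r)
    return y.transpose(0, 1, 3, 5, 2, 4).reshape(n, c * r * r, h // r, w // r)


def pixel_shuffle_array(x: np.ndarray, r: int) -> np.ndarray:
    n, c, h, w = x.shape
    if c % (r * r):
        raise ValueError(f"channels {c} not divisible by {r * r}")
    y = x.reshape(n, c // (r * r), r, r, h, w)
    return y.transpose(0, 1, 4, 2, 5, 3).reshape(n, c // (r * r), h * r, w * r)


def pixel_unshuffle(a: Tensor, r: int) -> Tensor:
    return _op(
        pixel_unshuffle_array(a.data, r), (a,), lambda g: (pixel_shuffle_array(g, r),)
    )


def pixel_shuffle(a: Tensor, r: int) -> Tensor:
    return _op(
        pixel_shuffle_array(a.data, r), (a,), lambda g: (pixel_unshuffle_array(g, r),)
    )


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    # xp: (N, C, Hp, Wp) -> (N, Ho, Wo, C, kh, kw)
    v = sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return v[:, :, ::stride, ::stride].transpose(0, 2, 3, 1, 4, 5)


def conv2d(x: Tensor, w: Tensor, b: Optional[Tensor], stride: int = 1,
           padding: int = 0) -> Tensor:
    """2D convolution (cross-correlation) over (N, C, H, W)."""
    n, c, h, wd = x.shape
    o, ci, kh, kw = w.shape
    if ci != c:
        raise ValueError(f"channel mismatch: input {c}, weight {ci}")
    xp = (
        np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        if padding
        else x.data
    )
    cols = _im2col(xp, kh, kw, stride)  # (N, Ho, Wo, C, kh, kw)
    ho, wo = cols.shape[1], cols.shape[2]
    cols2 = cols.reshape(n, ho * wo, c * kh * kw)
    wf = w.data.reshape(o, c * kh * kw)
    out = cols2 @ wf.T  # (N, L, O)
    if b is not None:
        out = out + b.data.reshape(1, 1, o)
    out = out.transpose(0, 2, 1).reshape(n, o, ho, wo)

    def bwd(g):
        gl = g.reshape(n, o, ho * wo).transpose(0, 2, 1)  # (N, L, O)
        gw = np.tensordot(gl, cols2, axes=([0, 1], [0, 1])).reshape(o, c, kh, kw)
        gb = gl.sum(axis=(0, 1)) if b is not None else None
        gcols = (gl @ wf).reshape(n, ho, wo, c, kh, kw)
        gxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                gxp[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += (
                    gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                )
        gx = gxp[:, :, padding : padding + h, padding : padding + wd] if padding else gxp
        return (gx, gw, gb) if b is not None else (gx, gw)

    parents = (x, w, b) if b is not None else (x, w)
    return _op(out, parents, bwd)


# ---------------------------------------------------------------------------
# parameters, layers, optimizer
# ---------------------------------------------------------------------------


class Conv2d:
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 1, padding: Optional[int] = None,
                 zero_init: bool = False):
        pad = (k // 2) if padding is None else padding
        scale = 0.0 if zero_init else np.sqrt(2.0 / (c_in * k * k))
        self.w = Tensor(rng.standard_normal((c_out, c_in, k, k)) * scale,
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride, self.padding = stride, pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, self.stride, self.padding)

    def params(self) -> List[Tensor]:
        return [self.w, self.b]


def collect_params(*modules) -> List[Tensor]:
    out: List[Tensor] = []
    for m in modules:
        out.extend(m.params())
    return out


class Adam:
    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: Tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def l1_loss(a: Tensor, b: Tensor) -> Tensor:
    return mean(abs_(add(a, mul_scalar(b, -1.0))))


def l2_loss(a: Tensor, b: Tensor) -> Tensor:
    return mean(square(add(a, mul_scalar(b, -1.0))))


def lsgan_loss(pred: Tensor, target: float) -> Tensor:
    return mean(square(add_scalar(pred, -target)))
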