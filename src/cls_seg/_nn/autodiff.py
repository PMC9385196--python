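"""Reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps a float32 ``numpy`` array together with an
optional gradient and a backward closure. Calling :meth:`Tensor.backward`
on a scalar loss runs the tape in reverse topological order.

Only the operations the models in this package require are implemented.
Convolution is evaluated as a loop over kernel taps, each tap a single
``einsum`` contraction — memory-light and BLAS-backed, which is the right
trade-off for the small feature maps used here.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = [
    "Tensor", "add", "mul", "concat", "conv2d", "linear", "relu", "sigmoid",
    "silu", "resize_bilinear", "interp_matrix", "global_avg_pool",
    "roi_align", "bce_with_logits", "smooth_l1",
]


def _as_array(x) -> np.ndarray:
    if isinstance(x, Tensor):
        raise TypeError("expected a raw array, got a Tensor")
    return np.asarray(x, dtype=np.float32)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
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
    """A node in the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    # -- construction helper for op results ------------------------------
    @staticmethod
    def _result(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
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
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
                node._parents = ()
                node._backward = None

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(other, -1.0) if isinstance(other, Tensor) else -_as_array(other))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / _as_array(other))

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g, self=self, axis=axis, keepdims=keepdims):
            if axis is None:
                gx = np.broadcast_to(g, self.data.shape)
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                gx = np.broadcast_to(g, self.data.shape)
            self._accumulate(gx)

        return Tensor._result(data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        data = self.data.reshape(*shape)

        def backward(g, self=self):
            self._accumulate(g.reshape(self.data.shape))

        return Tensor._result(data, (self,), backward)

    def item(self) -> float:
        return float(self.data)


def _lift(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(_as_array(x))


def add(a, b) -> Tensor:
    a, b = _lift(a), _lift(b)
    data = a.data + b.data

    def backward(g, a=a, b=b):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return Tensor._result(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _lift(a), _lift(b)
    data = a.data * b.data

    def backward(g, a=a, b=b):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return Tensor._result(data, (a, b), backward)


def power(a: Tensor, p: float) -> Tensor:
    data = a.data ** p

    def backward(g, a=a, p=p, data=data):
        a._accumulate(g * p * a.data ** (p - 1.0))

    return Tensor._result(data, (a,), backward)


def exp(x: Tensor) -> Tensor:
    data = np.exp(x.data)

    def backward(g, x=x, data=data):
        x._accumulate(g * data)

    return Tensor._result(data, (x,), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    data = np.where(mask, x.data, 0.0)

    def backward(g, x=x, mask=mask):
        x._accumulate(g * mask)

    return Tensor._result(data, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g, x=x, s=s):
        x._accumulate(g * s * (1.0 - s))

    return Tensor._result(s, (x,), backward)


def silu(x: Tensor) -> Tensor:
    """Swish / SiLU activation: x * sigmoid(x)."""
    s = 1.0 / (1.0 + np.exp(-x.data))
    data = x.data * s

    def backward(g, x=x, s=s):
        x._accumulate(g * (s * (1.0 + x.data * (1.0 - s))))

    return Tensor._result(data, (x,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_lift(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]

    def backward(g, tensors=tensors, sizes=sizes, axis=axis):
        offs = np.cumsum([0] + sizes)
        for t, lo, hi in zip(tensors, offs[:-1], offs[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return Tensor._result(data, tuple(tensors), backward)


# -- convolution ----------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, *, stride: int = 1,
           padding: int = 0, dilation: int = 1, groups: int = 1) -> Tensor:
    """2-D cross-correlation, NCHW layout, square stride/padding/dilation."""
    N, C, H, W = x.data.shape
    O, Cg, kh, kw = w.data.shape
    if C != Cg * groups or O % groups:
        raise ValueError(f"channel/group mismatch: x has {C} channels, "
                         f"weight {w.data.shape}, groups={groups}")
    Og = O // groups
    s, p, d = stride, padding, dilation
    ekh, ekw = kh + (kh - 1) * (d - 1), kw + (kw - 1) * (d - 1)
    Ho = (H + 2 * p - ekh) // s + 1
    Wo = (W + 2 * p - ekw) // s + 1
    if Ho <= 0 or Wo <= 0:
        raise ValueError("convolution output would be empty")
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    xg = xp.reshape(N, groups, Cg, *xp.shape[2:])
    wg = w.data.reshape(groups, Og, Cg, kh, kw)
    out = np.zeros((N, groups, Og, Ho, Wo), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            xs = xg[:, :, :, i * d: i * d + s * Ho: s, j * d: j * d + s * Wo: s]
            out += np.einsum("ngchw,goc->ngohw", xs, wg[:, :, :, i, j],
                             optimize=True)
    out = out.reshape(N, O, Ho, Wo)
    if b is not None:
        out += b.data.reshape(1, O, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g, x=x, w=w, b=b, xg=xg, wg=wg, shapes=(N, groups, Og, Cg, Ho, Wo, kh, kw, s, p, d)):
        N, G, Og, Cg, Ho, Wo, kh, kw, s, p, d = shapes
        gg = g.reshape(N, G, Og, Ho, Wo)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        need_x = x.requires_grad
        if need_x:
            gxp = np.zeros_like(xg)
        if w.requires_grad:
            gw = np.zeros_like(wg)
        for i in range(kh):
            for j in range(kw):
                sl = (slice(None), slice(None), slice(None),
                      slice(i * d, i * d + s * Ho, s),
                      slice(j * d, j * d + s * Wo, s))
                if w.requires_grad:
                    gw[:, :, :, i, j] = np.einsum(
                        "ngohw,ngchw->goc", gg, xg[sl], optimize=True)
                if need_x:
                    gxp[sl] += np.einsum(
                        "ngohw,goc->ngchw", gg, wg[:, :, :, i, j],
                        optimize=True)
        if w.requires_grad:
            w._accumulate(gw.reshape(w.data.shape))
        if need_x:
            gxp = gxp.reshape(N, G * Cg, *gxp.shape[3:])
            if p:
                gxp = gxp[:, :, p:-p, p:-p]
            x._accumulate(gxp)

    return Tensor._result(out, parents, backward)


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Affine map for 2-D inputs: (N, F) @ (F, O) + b."""
    data = x.data @ w.data
    if b is not None:
        data = data + b.data
    parents = (x, w) if b is None else (x, w, b)

    def backward(g, x=x, w=w, b=b):
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=0))
        if w.requires_grad:
            w._accumulate(x.data.T @ g)
        if x.requires_grad:
            x._accumulate(g @ w.data.T)

    return Tensor._result(data, parents, backward)


# -- resizing -------------------------------------------------------------

@lru_cache(maxsize=256)
def interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """1-D bilinear interpolation matrix (n_out x n_in), half-pixel centers.

    Row ``o`` holds the two weights that blend input samples into output
    sample ``o``; matrix multiplication applies the resize along one axis
    and the transpose applies its adjoint (used for gradients).
    """
    M = np.zeros((n_out, n_in), dtype=np.float32)
    src = (np.arange(n_out, dtype=np.float64) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    i0 = np.floor(src).astype(np.intp)
    i1 = np.minimum(i0 + 1, n_in - 1)
    f = (src - i0).astype(np.float32)
    rows = np.arange(n_out)
    np.add.at(M, (rows, i0), 1.0 - f)
    np.add.at(M, (rows, i1), f)
    return M


def resize_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Bilinear resize of an NCHW tensor (half-pixel convention)."""
    N, C, H, W = x.data.shape
    My = interp_matrix(H, out_h)
    Mx = interp_matrix(W, out_w)
    tmp = np.einsum("oh,nchw->ncow", My, x.data, optimize=True)
    data = np.einsum("pw,ncow->ncop", Mx, tmp, optimize=True)

    def backward(g, x=x, My=My, Mx=Mx):
        tmp = np.einsum("pw,ncop->ncow", Mx, g, optimize=True)
        x._accumulate(np.einsum("oh,ncow->nchw", My, tmp, optimize=True))

    return Tensor._result(data, (x,), backward)


def global_avg_pool(x: Tensor, keep_spatial: bool = False) -> Tensor:
    """Mean over H and W; optionally broadcast back to the input grid."""
    N, C, H, W = x.data.shape
    m = x.data.mean(axis=(2, 3), keepdims=True)
    data = np.broadcast_to(m, x.data.shape).copy() if keep_spatial else m

    def backward(g, x=x, keep=keep_spatial, H=H, W=W):
        if keep:
            g = g.sum(axis=(2, 3), keepdims=True)
        x._accumulate(np.broadcast_to(g / (H * W), x.data.shape))

    return Tensor._result(data, (x,), backward)


# -- ROI-Align ------------------------------------------------------------

def roi_align(x: Tensor, boxes: np.ndarray, out_size: int,
              spatial_scale: float = 1.0) -> Tensor:
    """ROI-Align pooling: bilinear sampling at exact fractional coordinates.

    ``boxes`` is (K, 5): (batch index, x0, y0, x1, y1) in input-image
    coordinates; ``spatial_scale`` maps them onto the feature grid. One
    sample per output bin, taken at the bin center — no quantization of
    box coordinates at any point.
    """
    N, C, H, W = x.data.shape
    boxes = np.asarray(boxes, dtype=np.float64)
    K = boxes.shape[0]
    P = out_size
    bi = boxes[:, 0].astype(np.intp)
    x0, y0, x1, y1 = (boxes[:, i] * spatial_scale for i in range(1, 5))
    # bin centers in feature coordinates (half-pixel sample positions)
    ty = (np.arange(P) + 0.5) / P
    sy = y0[:, None] + ty[None, :] * (y1 - y0)[:, None] - 0.5
    sx = x0[:, None] + ty[None, :] * (x1 - x0)[:, None] - 0.5
    sy = np.clip(sy, 0, H - 1)
    sx = np.clip(sx, 0, W - 1)
    y0i = np.floor(sy).astype(np.intp)
    x0i = np.floor(sx).astype(np.intp)
    y1i = np.minimum(y0i + 1, H - 1)
    x1i = np.minimum(x0i + 1, W - 1)
    fy = (sy - y0i).astype(np.float32)
    fx = (sx - x0i).astype(np.float32)

    xt = np.ascontiguousarray(x.data.transpose(0, 2, 3, 1))  # (N,H,W,C)
    b = bi[:, None, None]
    out = np.zeros((K, P, P, C), dtype=np.float32)
    combos = []
    for yi, wy in ((y0i, 1 - fy), (y1i, fy)):
        for xi, wx in ((x0i, 1 - fx), (x1i, fx)):
            wgt = (wy[:, :, None] * wx[:, None, :]).astype(np.float32)
            combos.append((yi, xi, wgt))
            out += wgt[..., None] * xt[b, yi[:, :, None], xi[:, None, :]]

    def backward(g, x=x, combos=combos, b=b, shape=(N, H, W, C)):
        g = np.ascontiguousarray(g.transpose(0, 2, 3, 1))  # (K,P,P,C)
        gxt = np.zeros(shape, dtype=np.float32)
        for yi, xi, wgt in combos:
            np.add.at(gxt, (b, yi[:, :, None], xi[:, None, :]),
                      wgt[..., None] * g)
        x._accumulate(gxt.transpose(0, 3, 1, 2))

    out = out.transpose(0, 3, 1, 2)
    return Tensor._result(np.ascontiguousarray(out), (x,), backward)


# -- losses ---------------------------------------------------------------

def bce_with_logits(logits: Tensor, targets: np.ndarray,
                    weights: np.ndarray | None = None) -> Tensor:
    """Numerically stable binary cross-entropy on logits (mean-reduced)."""
    z = logits.data
    t = _as_array(targets)
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    if weights is None:
        n = max(loss.size, 1)
        data = loss.sum() / n
    else:
        w = _as_array(weights)
        n = max(float(w.sum()), 1.0)
        data = (loss * w).sum() / n

    def backward(g, logits=logits, t=t, weights=weights, n=n):
        s = 1.0 / (1.0 + np.exp(-logits.data))
        gz = (s - t) / n
        if weights is not None:
            gz = gz * weights
        logits._accumulate(g * gz)

    return Tensor._result(np.float32(data), (logits,), backward)


def smooth_l1(pred: Tensor, target: np.ndarray, beta: float = 1.0) -> Tensor:
    """Huber / smooth-L1 loss, mean-reduced over all elements."""
    t = _as_array(target)
    diff = pred.data - t
    a = np.abs(diff)
    loss = np.where(a < beta, 0.5 * diff * diff / beta, a - 0.5 * beta)
    n = max(loss.size, 1)

    def backward(g, pred=pred, diff=diff, a=a, beta=beta, n=n):
        gd = np.where(a < beta, diff / beta, np.sign(diff)) / n
        pred._accumulate(g * gd)

    return Tensor._result(np.float32(loss.sum() / n), (pred,), backward)
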