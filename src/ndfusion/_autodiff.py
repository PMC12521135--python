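"""Minimal reverse-mode automatic differentiation on numpy arrays.

The networks in this package are small (tens of thousands of parameters,
desk-scale batches), so a straightforward define-by-run tape over numpy is
sufficient: every op records a closure that accumulates gradients into its
parents, and ``Tensor.backward`` walks the tape in reverse topological order.

Conventions
-----------
* All tensors are float64 unless constructed otherwise; gradients share the
  data dtype.
* Broadcasting follows numpy; binary ops reduce gradients back to the parent
  shape with :func:`_unbroadcast`.
* Only what the models need is implemented (no in-place ops, no views with
  aliasing semantics).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "Parameter", "cat", "conv3d", "maxpool3d", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum axes that were broadcast from size 1
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an attached gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _from_op(cls, data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- basic introspection ---------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- autograd --------------------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep (scans, epochs)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64).reshape(self.data.shape)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
            if node._parents:
                # free interior gradients/tape to bound memory
                node._backward = None

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad), self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad = self.grad + grad

    # -- arithmetic ------------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def backward(g):
            self._accum(g)
            other._accum(g)

        return Tensor._from_op(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return Tensor._from_op(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        return Tensor._from_op(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def backward(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / (other.data ** 2))

        return Tensor._from_op(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")

        def backward(g):
            self._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor._from_op(self.data ** exponent, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)

        def backward(g):
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 1:
                self._accum(g * b)
                other._accum(g * a)
                return
            ga = np.matmul(g, np.swapaxes(b, -1, -2)) if b.ndim > 1 else np.outer(g, b)
            gb = np.matmul(np.swapaxes(a, -1, -2), g) if a.ndim > 1 else np.outer(a, g)
            self._accum(_unbroadcast(ga, a.shape))
            other._accum(_unbroadcast(gb, b.shape))

        return Tensor._from_op(np.matmul(self.data, other.data), (self, other), backward)

    # -- elementwise nonlinearities --------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return Tensor._from_op(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return Tensor._from_op(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            self._accum(g * 0.5 / out_data)

        return Tensor._from_op(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor._from_op(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            self._accum(g * (1.0 - out_data ** 2))

        return Tensor._from_op(out_data, (self,), backward)

    def silu(self):
        """x * sigmoid(x) — the activation used throughout the network."""
        sig = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accum(g * (sig + self.data * sig * (1.0 - sig)))

        return Tensor._from_op(self.data * sig, (self,), backward)

    def softplus(self):
        # numerically stable log(1 + e^x)
        out_data = np.logaddexp(0.0, self.data)
        sig = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accum(g * sig)

        return Tensor._from_op(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return Tensor._from_op(self.data * mask, (self,), backward)

    # -- reductions ------------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        return Tensor._from_op(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            count = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def max(self, axis: int, keepdims: bool = False):
        """Max along one axis; gradient flows to the first argmax (ties broken low)."""
        idx = np.argmax(self.data, axis=axis)
        out_data = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis)
        if not keepdims:
            out_data = np.squeeze(out_data, axis=axis)

        def backward(g):
            gfull = np.zeros_like(self.data)
            gexp = g if keepdims else np.expand_dims(g, axis)
            np.put_along_axis(gfull, np.expand_dims(idx, axis), gexp, axis=axis)
            self._accum(gfull)

        return Tensor._from_op(out_data, (self,), backward)

    # -- shape manipulation ----------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def backward(g):
            self._accum(g.reshape(self.data.shape))

        return Tensor._from_op(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        return Tensor._from_op(self.data.transpose(axes), (self,), backward)

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, key):
        def backward(g):
            gfull = np.zeros_like(self.data)
            np.add.at(gfull, key, g)
            self._accum(gfull)

        return Tensor._from_op(self.data[key], (self,), backward)

    def expand_dims(self, axis: int):
        return self.reshape(*np.expand_dims(self.data, axis).shape)

    # -- composites ------------------------------------------------------------
    def logsumexp(self, axis: int, keepdims: bool = False):
        m = np.max(self.data, axis=axis, keepdims=True)  # constant shift
        shifted = self - Tensor(m)
        out = shifted.exp().sum(axis=axis, keepdims=True).log() + Tensor(m)
        if not keepdims:
            out = out.reshape(np.squeeze(out.data, axis=axis).shape)
        return out

    def softmax(self, axis: int = -1):
        axis = axis % self.data.ndim
        return (self - self.logsumexp(axis=axis, keepdims=True)).exp()

    def log_softmax(self, axis: int = -1):
        axis = axis % self.data.ndim
        return self - self.logsumexp(axis=axis, keepdims=True)


class Parameter(Tensor):
    """A trainable tensor (``requires_grad=True``)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def cat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    return Tensor._from_op(np.concatenate([t.data for t in tensors], axis=axis), tensors, backward)


# ---------------------------------------------------------------------------
# convolution / pooling primitives
# ---------------------------------------------------------------------------

def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None, padding: int = 1) -> Tensor:
    """3-D cross-correlation, stride 1.

    Parameters
    ----------
    x : (N, C, D, H, W)
    w : (O, C, kd, kh, kw)
    b : (O,) or None
    padding : symmetric zero padding on each spatial axis.
    """
    n, c, d, h, wd = x.data.shape
    o, c2, kd, kh, kw = w.data.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input has {c}, kernel expects {c2}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2, (padding,) * 2))
    do, ho, wo = d + 2 * padding - kd + 1, h + 2 * padding - kh + 1, wd + 2 * padding - kw + 1
    if min(do, ho, wo) < 1:
        raise ValueError(
            f"volume {(d, h, wd)} too small for kernel {(kd, kh, kw)} with padding {padding}"
        )
    win = np.lib.stride_tricks.sliding_window_view(xp, (kd, kh, kw), axis=(2, 3, 4))
    # win: (N, C, do, ho, wo, kd, kh, kw) -> cols (N*P, C*K)
    cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n * do * ho * wo, c * kd * kh * kw)
    wmat = w.data.reshape(o, -1).T  # (C*K, O)
    out_data = (cols @ wmat).reshape(n, do, ho, wo, o).transpose(0, 4, 1, 2, 3)
    if b is not None:
        out_data = out_data + b.data.reshape(1, o, 1, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gmat = g.transpose(0, 2, 3, 4, 1).reshape(n * do * ho * wo, o)
        if w.requires_grad:
            w._accum((cols.T @ gmat).T.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3, 4)))
        if x.requires_grad:
            dcols = (gmat @ wmat.T).reshape(n, do, ho, wo, c, kd, kh, kw)
            dxp = np.zeros_like(xp)
            for a in range(kd):
                for bb in range(kh):
                    for cc in range(kw):
                        dxp[:, :, a:a + do, bb:bb + ho, cc:cc + wo] += (
                            dcols[:, :, :, :, :, a, bb, cc].transpose(0, 4, 1, 2, 3)
                        )
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding, padding:-padding]
            x._accum(dxp)

    return Tensor._from_op(out_data, parents, backward)


def maxpool3d(x: Tensor, factor: int = 2) -> Tensor:
    """Non-overlapping max pooling; trailing remainder voxels are cropped."""
    n, c, d, h, w = x.data.shape
    dd, hh, ww = d // factor, h // factor, w // factor
    if min(dd, hh, ww) < 1:
        raise ValueError(f"volume {(d, h, w)} too small to pool by {factor}")
    xc = x.data[:, :, : dd * factor, : hh * factor, : ww * factor]
    blocks = xc.reshape(n, c, dd, factor, hh, factor, ww, factor)
    flat = blocks.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(n, c, dd, hh, ww, factor ** 3)
    idx = np.argmax(flat, axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
        gblocks = gflat.reshape(n, c, dd, hh, ww, factor, factor, factor).transpose(
            0, 1, 2, 5, 3, 6, 4, 7
        )
        gx = np.zeros_like(x.data)
        gx[:, :, : dd * factor, : hh * factor, : ww * factor] = gblocks.reshape(
            n, c, dd * factor, hh * factor, ww * factor
        )
        x._accum(gx)

    return Tensor._from_op(out_data, (x,), backward)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with decoupled-free (classic, L2-in-gradient) weight decay."""

    def __init__(self, params: Iterable[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.98), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        if not all(p.requires_grad for p in self.params):
            raise ValueError("all optimized tensors must require grad")
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
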