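"""Minimal reverse-mode automatic differentiation over numpy arrays.

The package trains a small fully convolutional network end to end through a
sparse random walk, so it needs gradients with respect to convolution weights,
affinity features and activation scores.  This module provides exactly the
tensor operations that pipeline uses: broadcasted arithmetic, exp/log/abs/pow,
reductions, gather, dense and constant-sparse matrix products, strided 2-D
convolution and separable bilinear resampling.

Design notes
------------
* A :class:`Tensor` wraps an ``ndarray`` plus an optional backward closure.
  :meth:`Tensor.backward` runs a topological sweep and accumulates ``.grad``
  on every tensor created with ``requires_grad=True``.
* Graph-structure constants (neighbour index matrices, interpolation weights)
  enter the graph as plain numpy/scipy objects; only the differentiable data
  path is taped.
* dtype follows the input arrays: float64 for gradient checks, float32 is the
  economical choice for training loops.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import sparse as _sp

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "stack",
    "conv2d",
    "resize_bilinear",
    "sparse_matmul",
]


class Tensor:
    """An array node in the reverse-mode tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _backward: Callable[[np.ndarray], None] | None = None,
        _parents: tuple["Tensor", ...] = (),
    ):
        self.data = np.asarray(data)
        if self.data.dtype.kind != "f":
            self.data = self.data.astype(np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = _backward
        self._parents = _parents

    # ------------------------------------------------------------------ basic
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    # ------------------------------------------------------------------ tape
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of ``self`` into every antecedent tensor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative DFS post-order (graphs can be thousands of nodes deep)
        while stack:
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [p for p in node._parents if id(p) not in seen]
            if unvisited:
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(stack.pop())
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    if pg is None:
                        continue
                    key = id(parent)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg

    # ------------------------------------------------------------- operators
    def __add__(self, other):
        return _binop(self, other, np.add, lambda g, a, b: (g, g))

    __radd__ = __add__

    def __sub__(self, other):
        return _binop(self, other, np.subtract, lambda g, a, b: (g, -g))

    def __rsub__(self, other):
        return as_tensor(other) - self

    def __mul__(self, other):
        return _binop(self, other, np.multiply, lambda g, a, b: (g * b, g * a))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return _binop(
            self, other, np.divide, lambda g, a, b: (g / b, -g * a / (b * b))
        )

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __neg__(self):
        return _unop(self, np.negative, lambda g, x: -g)

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        e = float(exponent)
        return _unop(self, lambda x: np.power(x, e), lambda g, x: g * e * np.power(x, e - 1.0))

    def __getitem__(self, idx):
        def bwd(g, x, _idx=idx):
            out = np.zeros_like(x)
            np.add.at(out, _idx, g)
            return out

        return _unop(self, lambda x: x[idx], bwd)

    # ------------------------------------------------------------- math ops
    def exp(self) -> "Tensor":
        out = np.exp(self.data)
        return _from(self, out, lambda g, x: g * out)

    def log(self) -> "Tensor":
        return _unop(self, np.log, lambda g, x: g / x)

    def abs(self) -> "Tensor":
        return _unop(self, np.abs, lambda g, x: g * np.sign(x))

    def clamp_min(self, lo: float) -> "Tensor":
        """Lower clamp; gradient flows only where the input is above ``lo``."""
        return _unop(
            self,
            lambda x: np.maximum(x, lo),
            lambda g, x: g * (x > lo),
        )

    def relu(self) -> "Tensor":
        return _unop(self, lambda x: np.maximum(x, 0.0), lambda g, x: g * (x > 0))

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def bwd(g, x, _axis=axis, _keep=keepdims):
            if _axis is not None and not _keep:
                g = np.expand_dims(g, _axis)
            return np.broadcast_to(g, x.shape).astype(x.dtype, copy=False)

        return _unop(self, lambda x: np.sum(x, axis=axis, keepdims=keepdims), bwd)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self) -> "Tensor":
        """Global maximum; gradient routed to the first arg-max entry."""
        flat_idx = int(np.argmax(self.data))

        def bwd(g, x):
            out = np.zeros_like(x)
            out.flat[flat_idx] = g
            return out

        return _unop(self, lambda x: np.asarray(np.max(x)), bwd)

    def take(self, flat_indices: np.ndarray) -> "Tensor":
        """Gather entries of the flattened tensor."""
        idx = np.asarray(flat_indices, dtype=np.intp)

        def bwd(g, x):
            out = np.zeros_like(x)
            np.add.at(out.reshape(-1), idx, g)
            return out

        return _unop(self, lambda x: x.reshape(-1)[idx], bwd)

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bwd(g, x):
            return g.reshape(x.shape)

        return _unop(self, lambda x: x.reshape(shape), bwd)

    def transpose(self, *axes) -> "Tensor":
        axes = axes or None
        inv = np.argsort(axes) if axes else None

        def bwd(g, x):
            return np.transpose(g, inv)

        return _unop(self, lambda x: np.transpose(x, axes), bwd)

    @property
    def T(self) -> "Tensor":
        return self.transpose()

    def matmul(self, other: "Tensor") -> "Tensor":
        other = as_tensor(other)
        out = self.data @ other.data

        def bwd(g):
            ga = g @ other.data.T if self.requires_grad or self._backward else None
            gb = self.data.T @ g if other.requires_grad or other._backward else None
            return ((self, ga), (other, gb))

        return Tensor(out, _backward=bwd, _parents=(self, other))

    __matmul__ = matmul

    def softmax(self, axis: int = 0) -> "Tensor":
        """Numerically stable softmax along ``axis``."""
        shifted = self - np.max(self.data, axis=axis, keepdims=True)
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------- helpers
def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _binop(a, b, fwd, grads) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = fwd(a.data, b.data)

    def bwd(g):
        ga, gb = grads(g, a.data, b.data)
        return (
            (a, _unbroadcast(ga, a.data.shape) if ga is not None else None),
            (b, _unbroadcast(gb, b.data.shape) if gb is not None else None),
        )

    return Tensor(out, _backward=bwd, _parents=(a, b))


def _unop(x: Tensor, fwd, grad) -> Tensor:
    out = fwd(x.data)

    def bwd(g):
        return ((x, grad(g, x.data)),)

    return Tensor(out, _backward=bwd, _parents=(x,))


def _from(x: Tensor, out: np.ndarray, grad) -> Tensor:
    def bwd(g):
        return ((x, grad(g, x.data)),)

    return Tensor(out, _backward=bwd, _parents=(x,))


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        parts = np.split(g, splits, axis=axis)
        return tuple(zip(tensors, parts))

    return Tensor(out, _backward=bwd, _parents=tuple(tensors))


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.stack([t.data for t in tensors], axis=axis)

    def bwd(g):
        parts = np.moveaxis(g, axis, 0)
        return tuple((t, parts[i]) for i, t in enumerate(tensors))

    return Tensor(out, _backward=bwd, _parents=tuple(tensors))


def sparse_matmul(mat: _sp.spmatrix, x: Tensor) -> Tensor:
    """Product of a *constant* sparse matrix with a differentiable tensor.

    Used for neighbour gathers and segment sums of the affinity graph; the
    sparsity pattern is pure grid structure and carries no gradient.
    """
    x = as_tensor(x)
    out = mat @ x.data

    def bwd(g):
        return ((x, mat.T @ g),)

    return Tensor(np.asarray(out), _backward=bwd, _parents=(x,))


# --------------------------------------------------------------- conv2d
def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (k, k), axis=(1, 2))[:, ::stride, ::stride]
    # win: (c, oh, ow, k, k) -> (oh*ow, c*k*k)
    oh, ow = win.shape[1], win.shape[2]
    cols = win.transpose(1, 2, 0, 3, 4).reshape(oh * ow, c * k * k)
    return np.ascontiguousarray(cols), oh, ow


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution, input ``(C, H, W)``, weight ``(O, C, k, k)``."""
    x, weight = as_tensor(x), as_tensor(weight)
    o, c, k, _ = weight.shape
    cols, oh, ow = _im2col(x.data, k, stride, pad)
    wmat = weight.data.reshape(o, c * k * k)
    out = (cols @ wmat.T).T.reshape(o, oh, ow)
    if bias is not None:
        out = out + bias.data.reshape(o, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def bwd(g):
        gmat = g.reshape(o, oh * ow)  # (o, n)
        gw = (gmat @ cols).reshape(weight.shape)
        gcols = gmat.T @ wmat  # (n, c*k*k)
        gx = _col2im(gcols, x.data.shape, k, stride, pad, oh, ow)
        res = [(x, gx), (weight, gw)]
        if bias is not None:
            res.append((bias, gmat.sum(axis=1)))
        return tuple(res)

    return Tensor(out, _backward=bwd, _parents=parents)


def _col2im(gcols: np.ndarray, xshape, k: int, stride: int, pad: int,
            oh: int, ow: int) -> np.ndarray:
    c, h, w = xshape
    gpad = np.zeros((c, h + 2 * pad, w + 2 * pad), dtype=gcols.dtype)
    gwin = gcols.reshape(oh, ow, c, k, k)
    for di in range(k):
        for dj in range(k):
            gpad[:, di:di + oh * stride:stride, dj:dj + ow * stride:stride] += (
                gwin[:, :, :, di, dj].transpose(2, 0, 1)
            )
    return gpad[:, pad:pad + h, pad:pad + w] if pad else gpad


# ------------------------------------------------------- bilinear resize
def _interp_matrix(n_in: int, n_out: int, dtype=np.float64) -> np.ndarray:
    """Dense 1-D bilinear interpolation matrix (pixel-centre convention)."""
    m = np.zeros((n_out, n_in), dtype=dtype)
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    scale = n_in / n_out
    pos = (np.arange(n_out) + 0.5) * scale - 0.5
    pos = np.clip(pos, 0.0, n_in - 1.0)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = pos - lo
    m[np.arange(n_out), lo] += 1.0 - frac
    m[np.arange(n_out), hi] += frac
    return m


def resize_bilinear(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Separable bilinear resize of a ``(C, h, w)`` tensor to ``(C, H, W)``."""
    x = as_tensor(x)
    h_out, w_out = size
    _, h_in, w_in = x.shape
    mh = _interp_matrix(h_in, h_out, x.dtype)
    mw = _interp_matrix(w_in, w_out, x.dtype)
    out = np.einsum("ij,cjk,lk->cil", mh, x.data, mw, optimize=True)

    def bwd(g):
        gx = np.einsum("ji,cjk,kl->cil", mh, g, mw, optimize=True)
        return ((x, gx),)

    return Tensor(out, _backward=bwd, _parents=(x,))


# ----------------------------------------------------------- parameters
class Parameter(Tensor):
    """A leaf tensor updated by an optimizer."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Tiny parameter container, enough for checkpointing and optimizers."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for value in vars(self).values():
            if isinstance(value, Parameter):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        return {str(i): p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("checkpoint does not match model parameter count")
        for i, p in enumerate(params):
            arr = np.asarray(state[str(i)])
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {i} shape mismatch")
            p.data = arr.astype(p.data.dtype, copy=True)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


class Adam:
    """Adam with the standard bias correction."""

    def __init__(self, params: Iterable[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
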