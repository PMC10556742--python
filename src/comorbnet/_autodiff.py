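"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the primitive set the meta-path attention model needs:
dense linear algebra, element-wise nonlinearities, segment (grouped)
softmax/sum for per-target attention, integer-array gather, and a complex
rotation primitive for the relational rotation encoder.  Everything runs in
float64; gradients are accumulated by topological traversal of the tape.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "add", "sub", "mul", "matmul", "tensor_sum", "tensor_mean",
    "tanh", "elu", "leaky_relu", "log_sigmoid", "softmax",
    "segment_softmax", "segment_sum", "take_rows", "reshape",
    "concat", "complex_rotate", "neg", "scale",
]


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


class Tensor:
    """A numpy array plus a gradient slot and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None,
                 name: str = ""):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad}, name={self.name!r})"

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad=None) -> None:
        """Accumulate gradients of self w.r.t. every reachable parameter."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient "
                                 "requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
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
        self.grad = _as_array(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray) -> None:
        # closures hand out freshly computed arrays (or views never mutated
        # in place), so storing without a defensive copy is safe
        if self.grad is None:
            self.grad = g if isinstance(g, np.ndarray) else _as_array(g)
        else:
            self.grad = self.grad + g


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcast gradient back to `shape`."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def _make(data, parents, backward) -> Tensor:
    req = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req,
                  parents=[p for p in parents if p.requires_grad],
                  backward=backward if req else None)


# ---------------------------------------------------------------------------
# arithmetic

def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def neg(a) -> Tensor:
    a = _wrap(a)

    def backward(g):
        a._accum(-g)

    return _make(-a.data, (a,), backward)


def sub(a, b) -> Tensor:
    return add(a, neg(_wrap(b)))


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def scale(a, c: float) -> Tensor:
    a = _wrap(a)

    def backward(g):
        a._accum(g * c)

    return _make(a.data * c, (a,), backward)


def matmul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            if b.data.ndim == 1:
                a._accum(np.outer(g, b.data) if a.data.ndim == 2 else g * b.data)
            else:
                a._accum(g @ b.data.T)
        if b.requires_grad:
            if a.data.ndim == 1:
                b._accum(np.outer(a.data, g) if b.data.ndim == 2 else a.data * g)
            else:
                b._accum(a.data.T @ g)

    return _make(out_data, (a, b), backward)


def tensor_sum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _wrap(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        if axis is None:
            a._accum(np.broadcast_to(g, a.data.shape).copy())
        else:
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.data.shape).copy())

    return _make(out_data, (a,), backward)


def tensor_mean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _wrap(a)
    n = a.data.size if axis is None else a.data.shape[axis]
    return scale(tensor_sum(a, axis=axis, keepdims=keepdims), 1.0 / n)


# ---------------------------------------------------------------------------
# nonlinearities

def tanh(a) -> Tensor:
    a = _wrap(a)
    out_data = np.tanh(a.data)

    def backward(g):
        a._accum(g * (1.0 - out_data ** 2))

    return _make(out_data, (a,), backward)


def elu(a, alpha: float = 1.0) -> Tensor:
    a = _wrap(a)
    neg_part = alpha * np.expm1(np.minimum(a.data, 0.0))
    out_data = np.where(a.data > 0, a.data, neg_part)

    def backward(g):
        a._accum(g * np.where(a.data > 0, 1.0, neg_part + alpha))

    return _make(out_data, (a,), backward)


def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = _wrap(a)
    out_data = np.where(a.data > 0, a.data, slope * a.data)

    def backward(g):
        a._accum(g * np.where(a.data > 0, 1.0, slope))

    return _make(out_data, (a,), backward)


def log_sigmoid(a) -> Tensor:
    """log sigma(x), evaluated as min(x,0) - log1p(exp(-|x|)) for stability."""
    a = _wrap(a)
    x = a.data
    out_data = np.minimum(x, 0.0) - np.log1p(np.exp(-np.abs(x)))

    def backward(g):
        # d/dx log sigma(x) = sigma(-x)
        a._accum(g / (1.0 + np.exp(x)))

    return _make(out_data, (a,), backward)


def softmax(a, axis: int = -1) -> Tensor:
    """Numerically stable softmax (max-subtraction)."""
    a = _wrap(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        a._accum(out_data * (g - dot))

    return _make(out_data, (a,), backward)


# ---------------------------------------------------------------------------
# segment (grouped) operations: attention over a variable number of
# meta-path instances per target node


def _scatter_rows(g: np.ndarray, idx: np.ndarray, n_rows: int) -> np.ndarray:
    """Sum rows of `g` into an (n_rows, ...) array by integer index.

    Implemented with a stable sort plus ufunc.reduceat, which is markedly
    faster than np.add.at for the repeated-index scatters the model needs.
    """
    out = np.zeros((n_rows,) + g.shape[1:])
    if len(idx) == 0:
        return out
    if np.all(idx[1:] >= idx[:-1]):
        sidx, sg = idx, g
    else:
        order = np.argsort(idx, kind="stable")
        sidx, sg = idx[order], g[order]
    starts = np.flatnonzero(np.r_[True, sidx[1:] != sidx[:-1]])
    out[sidx[starts]] = np.add.reduceat(sg, starts, axis=0)
    return out


def _segment_reduce_max(x: np.ndarray, idx: np.ndarray, n_rows: int,
                        ) -> np.ndarray:
    out = np.full((n_rows,) + x.shape[1:], -np.inf)
    if len(idx) == 0:
        return out
    if np.all(idx[1:] >= idx[:-1]):
        sidx, sx = idx, x
    else:
        order = np.argsort(idx, kind="stable")
        sidx, sx = idx[order], x[order]
    starts = np.flatnonzero(np.r_[True, sidx[1:] != sidx[:-1]])
    out[sidx[starts]] = np.maximum.reduceat(sx, starts, axis=0)
    return out


def segment_softmax(logits, segments: np.ndarray, num_segments: int) -> Tensor:
    """Softmax over rows sharing a segment id.

    logits: (N, ...) tensor; segments: (N,) int array.  Rows in the same
    segment are jointly normalized (per trailing component), with
    max-subtraction within each segment for stability.  Empty segments are
    simply absent from the output rows.
    """
    a = _wrap(logits)
    x = a.data
    seg_max = _segment_reduce_max(x, segments, num_segments)
    e = np.exp(x - seg_max[segments])
    denom = _scatter_rows(e, segments, num_segments)
    out_data = e / denom[segments]

    def backward(g):
        dot = _scatter_rows(g * out_data, segments, num_segments)
        a._accum(out_data * (g - dot[segments]))

    return _make(out_data, (a,), backward)


def segment_sum(a, segments: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of `a` grouped by segment id -> (num_segments, ...)."""
    a = _wrap(a)
    out_data = _scatter_rows(a.data, segments, num_segments)

    def backward(g):
        a._accum(g[segments])

    return _make(out_data, (a,), backward)


def take_rows(a, idx: np.ndarray) -> Tensor:
    """Gather rows by integer index (repeats allowed)."""
    a = _wrap(a)
    idx = np.asarray(idx, dtype=np.intp)
    out_data = a.data[idx]

    def backward(g):
        a._accum(_scatter_rows(g, idx, a.data.shape[0]))

    return _make(out_data, (a,), backward)


def reshape(a, shape) -> Tensor:
    a = _wrap(a)
    old_shape = a.data.shape

    def backward(g):
        a._accum(g.reshape(old_shape))

    return _make(a.data.reshape(shape), (a,), backward)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    return _make(out_data, tuple(tensors), backward)


def complex_rotate(o, theta, sign: float = 1.0) -> Tensor:
    """Element-wise complex product of `o` with the unit phasor e^{i*sign*theta}.

    `o` has even last dimension 2m read as m complex components in adjacent
    (real, imag) pairs; `theta` has shape (m,).  Parameterising the relation
    vector by its phase keeps it on the unit circle by construction.
    """
    o, theta = _wrap(o), _wrap(theta)
    if o.data.shape[-1] != 2 * theta.data.shape[-1]:
        raise ValueError(f"vector dim {o.data.shape[-1]} is not twice the "
                         f"phase dim {theta.data.shape[-1]}")
    # adjacent (real, imag) float64 pairs share numpy's complex128 layout,
    # so the rotation is a single native complex multiply
    r = np.exp(1j * sign * theta.data)
    o_c = np.ascontiguousarray(o.data).view(np.complex128)
    out_c = o_c * r
    out_data = out_c.view(np.float64)

    def backward(g):
        g_c = np.ascontiguousarray(g).view(np.complex128)
        if o.requires_grad:
            # d out / d o is multiplication by conj(r)
            o._accum((g_c * np.conj(r)).view(np.float64))
        if theta.requires_grad:
            # d out / d phi = i * out  =>  dphi = Im(conj(out) . g) per column
            dphi = np.imag(np.conj(out_c) * g_c)
            dphi = dphi.reshape(-1, theta.data.shape[-1]).sum(axis=0)
            theta._accum(sign * dphi)

    return _make(out_data, (o, theta), backward)
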