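"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tensor engine: every operation the signal networks in
this package need (1D convolution, batched matrix products, normalisation
statistics, gated recurrences) is available as a differentiable primitive,
and nothing else.  Gradients are accumulated by a topological-order sweep
over the recorded computation graph; correctness of every primitive is
checked against central finite differences in the test suite.

All arithmetic is float64 internally - desk-scale models are small enough
that the extra width costs little and it keeps finite-difference gradient
checks tight.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat"]


def _sum_to_shape(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcast gradient back to the shape of its source operand."""
    if grad.shape == shape:
        return grad
    nd_extra = grad.ndim - len(shape)
    if nd_extra > 0:
        grad = grad.sum(axis=tuple(range(nd_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the closure that back-propagates into its parents."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        parents = tuple(p for p in parents if isinstance(p, Tensor))
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Back-propagate from this tensor (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: recurrent graphs are thousands deep
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
        if grad is None:
            grad = np.ones_like(self.data)
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
                node._parents = ()
                node._backward = None

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_sum_to_shape(g, a.shape))
            if b.requires_grad:
                b._accum(_sum_to_shape(g, b.shape))

        return Tensor._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            a._accum(-g)

        return Tensor._make(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_sum_to_shape(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_sum_to_shape(g * a.data, b.shape))

        return Tensor._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * as_tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        a = self
        p = float(exponent)
        out_data = a.data**p

        def backward(g):
            a._accum(g * p * a.data ** (p - 1.0))

        return Tensor._make(out_data, (a,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self, other

        if a.data.ndim < 2 or b.data.ndim < 2:
            raise ValueError("matmul requires operands with ndim >= 2")

        def backward(g):
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                a._accum(_sum_to_shape(ga, a.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                b._accum(_sum_to_shape(gb, b.shape))

        return Tensor._make(np.matmul(a.data, b.data), (a, b), backward)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.shape).copy())

        return Tensor._make(out_data, (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ---------------------------------------------------------- shape surgery
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old_shape = a.shape

        def backward(g):
            a._accum(g.reshape(old_shape))

        return Tensor._make(a.data.reshape(shape), (a,), backward)

    def swapaxes(self, ax1: int, ax2: int):
        a = self

        def backward(g):
            a._accum(np.swapaxes(g, ax1, ax2))

        return Tensor._make(np.swapaxes(a.data, ax1, ax2), (a,), backward)

    def __getitem__(self, key):
        a = self

        def backward(g):
            full = np.zeros_like(a.data)
            np.add.at(full, key, g)
            a._accum(full)

        return Tensor._make(a.data[key], (a,), backward)

    def pad_last(self, left: int, right: int):
        """Zero-pad the trailing (time) axis."""
        a = self
        if left == 0 and right == 0:
            return a * 1.0
        width = [(0, 0)] * (a.ndim - 1) + [(left, right)]
        L = a.shape[-1]

        def backward(g):
            sl = (slice(None),) * (a.ndim - 1) + (slice(left, left + L),)
            a._accum(g[sl])

        return Tensor._make(np.pad(a.data, width), (a,), backward)

    # ------------------------------------------------------------- pointwise
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            a._accum(g * out_data)

        return Tensor._make(out_data, (a,), backward)

    def log(self):
        a = self

        def backward(g):
            a._accum(g / a.data)

        return Tensor._make(np.log(a.data), (a,), backward)

    def sqrt(self):
        return self**0.5

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def backward(g):
            a._accum(g * (1.0 - out_data**2))

        return Tensor._make(out_data, (a,), backward)

    def sigmoid(self):
        a = self
        out_data = _sigmoid(a.data)

        def backward(g):
            a._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (a,), backward)

    def logsigmoid(self):
        """Numerically stable log(sigmoid(x))."""
        a = self
        x = a.data
        out_data = np.where(x >= 0, -np.log1p(np.exp(-np.abs(x))), x - np.log1p(np.exp(-np.abs(x))))

        def backward(g):
            a._accum(g * (1.0 - _sigmoid(x)))

        return Tensor._make(out_data, (a,), backward)

    def silu(self):
        return self * self.sigmoid()

    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g):
            a._accum(g * mask)

        return Tensor._make(a.data * mask, (a,), backward)

    def softmax(self, axis: int = -1):
        a = self
        z = a.data - a.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            a._accum(out_data * (g - dot))

        return Tensor._make(out_data, (a,), backward)

    def log_softmax(self, axis: int = -1):
        a = self
        z = a.data - a.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        out_data = z - lse
        soft = np.exp(out_data)

        def backward(g):
            a._accum(g - soft * g.sum(axis=axis, keepdims=True))

        return Tensor._make(out_data, (a,), backward)

    # --------------------------------------------------------- signal-specific
    def conv1d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0):
        """1D cross-correlation: (B, Cin, L) * (Cout, Cin, K) -> (B, Cout, Lout)."""
        a, w = self, weight
        B, Cin, L = a.shape
        Cout, Cin_w, K = w.shape
        if Cin != Cin_w:
            raise ValueError(f"conv1d channel mismatch: input {Cin}, weight {Cin_w}")
        xp = np.pad(a.data, ((0, 0), (0, 0), (padding, padding))) if padding else a.data
        Lp = xp.shape[-1]
        Lout = (Lp - K) // stride + 1
        cols = np.lib.stride_tricks.sliding_window_view(xp, K, axis=2)[:, :, ::stride, :]
        # cols: (B, Cin, Lout, K)
        out_data = np.einsum("bclk,ock->bol", cols, w.data, optimize=True)
        if bias is not None:
            out_data = out_data + bias.data[None, :, None]

        def backward(g):
            if w.requires_grad:
                w._accum(np.einsum("bol,bclk->ock", g, cols, optimize=True))
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2)))
            if a.requires_grad:
                gcols = np.einsum("bol,ock->bclk", g, w.data, optimize=True)
                gxp = np.zeros((B, Cin, Lp))
                for k in range(K):
                    gxp[:, :, k:k + stride * Lout:stride] += gcols[:, :, :, k]
                a._accum(gxp[:, :, padding:padding + L] if padding else gxp)

        parents = (a, w) if bias is None else (a, w, bias)
        return Tensor._make(out_data, parents, backward)

    def upsample_nearest(self, factor: int):
        """Repeat each time sample `factor` times along the last axis."""
        a = self

        def backward(g):
            a._accum(g.reshape(*a.shape, factor).sum(axis=-1))

        return Tensor._make(np.repeat(a.data, factor, axis=-1), (a,), backward)

    def maxpool1d(self, kernel: int):
        """Non-overlapping max pooling (stride == kernel) on the last axis."""
        a = self
        B_shape = a.shape[:-1]
        L = a.shape[-1]
        if L % kernel:
            raise ValueError(f"length {L} not divisible by pool kernel {kernel}")
        blocks = a.data.reshape(*B_shape, L // kernel, kernel)
        arg = blocks.argmax(axis=-1)
        out_data = np.take_along_axis(blocks, arg[..., None], axis=-1)[..., 0]

        def backward(g):
            gb = np.zeros_like(blocks)
            np.put_along_axis(gb, arg[..., None], g[..., None], axis=-1)
            a._accum(gb.reshape(a.shape))

        return Tensor._make(out_data, (a,), backward)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tuple(tensors), backward)


def embedding_lookup(table: Tensor, indices: np.ndarray) -> Tensor:
    """Row lookup into an embedding table with scatter-add backward."""
    idx = np.asarray(indices, dtype=np.intp)

    def backward(g):
        full = np.zeros_like(table.data)
        np.add.at(full, idx, g)
        table._accum(full)

    return Tensor._make(table.data[idx], (table,), backward)
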