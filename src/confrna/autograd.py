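"""Minimal reverse-mode automatic differentiation on numpy arrays.

The network layers in this package (convolution, LSTM gates, attention)
are expressed as compositions of the primitives defined here.  Each
primitive records its parents and a backward closure; :meth:`Tensor.backward`
runs a topological sweep accumulating gradients into ``Tensor.grad``.

Design constraints:

- float64 throughout, so finite-difference gradient checks hold tight
  tolerances and runs are bitwise reproducible across identical seeds.
- Broadcasting follows numpy semantics; gradients of broadcast operands
  are summed back down to the operand's shape.
- Only the indexing patterns the model needs are supported for
  ``__getitem__`` (basic slicing / integer indexing without repeats);
  gather-with-repeats goes through the dedicated :func:`embedding` op.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concatenate",
    "conv1d_raw",
    "cross_entropy",
    "embedding",
    "log_softmax",
    "relu",
    "sigmoid",
    "softmax",
    "tanh",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """An ndarray node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # -- introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autodiff ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of ``self`` w.r.t. every reachable leaf."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed gradient requires a scalar")
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
            for parent in node._parents:
                stack.append((parent, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray, own: bool = False) -> None:
        """Add ``grad`` into ``self.grad``.

        ``own=True`` promises the caller freshly allocated ``grad`` for this
        parent alone, so the first accumulation can keep it without copying.
        """
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = grad if own else grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                ga = _unbroadcast(g, self.shape)
                self._accumulate(ga, own=ga is not g)
            if other.requires_grad:
                gb = _unbroadcast(g, other.shape)
                other._accumulate(gb, own=gb is not g)

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accumulate(-g, own=True)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape), own=True)
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape), own=True)

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            raise TypeError("tensor/tensor division is not needed; multiply by a reciprocal")
        return self * (1.0 / other)

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(np.matmul(self.data, other.data), parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(
                    _unbroadcast(np.matmul(g, np.swapaxes(other.data, -1, -2)), self.shape),
                    own=True,
                )
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(np.matmul(np.swapaxes(self.data, -1, -2), g), other.shape),
                    own=True,
                )

        out._backward = bwd
        return out

    # -- shape ops -----------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), parents=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.shape))
        return out

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inverse = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))
        out._backward = lambda g: self._accumulate(g.transpose(inverse))
        return out

    def __getitem__(self, key) -> "Tensor":
        out = Tensor(self.data[key], parents=(self,))

        def bwd(g):
            # keys are basic (no repeated indices), so in-place += is exact;
            # accumulating directly into .grad avoids a dense zero alloc per slice
            if not self.requires_grad:
                return
            if self.grad is None:
                self.grad = np.zeros_like(self.data)
            self.grad[key] += g

        out._backward = bwd
        return out

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy(), own=True)

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


# ---------------------------------------------------------------------
# elementwise nonlinearities
# ---------------------------------------------------------------------

def exp(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = Tensor(np.exp(x.data), parents=(x,))
    out._backward = lambda g: x._accumulate(g * out.data, own=True)
    return out


def log(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = Tensor(np.log(x.data), parents=(x,))
    out._backward = lambda g: x._accumulate(g / x.data, own=True)
    return out


def tanh(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = Tensor(np.tanh(x.data), parents=(x,))
    out._backward = lambda g: x._accumulate(g * (1.0 - out.data**2), own=True)
    return out


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = Tensor(1.0 / (1.0 + np.exp(-x.data)), parents=(x,))
    out._backward = lambda g: x._accumulate(g * out.data * (1.0 - out.data), own=True)
    return out


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = Tensor(np.maximum(x.data, 0.0), parents=(x,))
    out._backward = lambda g: x._accumulate(g * (x.data > 0.0), own=True)
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along ``axis``."""
    x = as_tensor(x)
    y = x.data - x.data.max(axis=axis, keepdims=True)
    np.exp(y, out=y)
    y /= y.sum(axis=axis, keepdims=True)
    out = Tensor(y, parents=(x,))

    def bwd(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        x._accumulate((g - dot) * y, own=True)

    out._backward = bwd
    return out


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    logz = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out = Tensor(shifted - logz, parents=(x,))

    def bwd(g):
        soft = np.exp(out.data)
        x._accumulate(g - soft * g.sum(axis=axis, keepdims=True), own=True)

    out._backward = bwd
    return out


# ---------------------------------------------------------------------
# structural ops
# ---------------------------------------------------------------------

def concatenate(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, start, stop in zip(tensors, offsets[:-1], offsets[1:]):
            index = [slice(None)] * g.ndim
            index[axis] = slice(start, stop)
            t._accumulate(g[tuple(index)])

    out._backward = bwd
    return out


def embedding(weight: Tensor, indices: np.ndarray) -> Tensor:
    """Row gather ``weight[indices]`` with scatter-add backward."""
    weight = as_tensor(weight)
    indices = np.asarray(indices)
    out = Tensor(weight.data[indices], parents=(weight,))

    def bwd(g):
        full = np.zeros_like(weight.data)
        np.add.at(full, indices.reshape(-1), g.reshape(-1, weight.data.shape[-1]))
        weight._accumulate(full, own=True)

    out._backward = bwd
    return out


def conv1d_raw(x: Tensor, w: Tensor, b: Tensor, dilation: int = 1) -> Tensor:
    """Same-padded dilated 1-D convolution (cross-correlation).

    x: (..., L, C_in); w: (K, C_in, C_out); b: (C_out,).
    Output length equals input length for any kernel size and dilation;
    padding splits the receptive-field overhang left/right as evenly as
    possible (left gets the smaller half for even spans).
    """
    x, w, b = as_tensor(x), as_tensor(w), as_tensor(b)
    if x.shape[-1] != w.shape[1]:
        raise ValueError(
            f"channel mismatch: input has {x.shape[-1]} channels, kernel fan-in is {w.shape[1]}"
        )
    kernel, c_in, c_out = w.shape
    length = x.shape[-2]
    span = (kernel - 1) * dilation + 1
    left = (span - 1) // 2
    right = span - 1 - left
    squeeze = x.ndim == 2
    data = x.data[None] if squeeze else x.data
    batch_shape = data.shape[:-2]
    data = data.reshape(-1, length, c_in)

    padded = np.pad(data, ((0, 0), (left, right), (0, 0)))
    gather = np.arange(length)[:, None] + np.arange(kernel)[None, :] * dilation  # (L, K)
    cols = padded[:, gather, :]  # (B, L, K, C_in)
    flat = cols.reshape(-1, kernel * c_in)
    y = (flat @ w.data.reshape(kernel * c_in, c_out) + b.data).reshape(-1, length, c_out)
    y = y.reshape(batch_shape + (length, c_out))
    out = Tensor(y[0] if squeeze else y, parents=(x, w, b))

    def bwd(g):
        g2 = (g[None] if squeeze else g).reshape(-1, length, c_out)
        gflat = g2.reshape(-1, c_out)
        if w.requires_grad:
            w._accumulate((flat.T @ gflat).reshape(w.shape), own=True)
        if b.requires_grad:
            b._accumulate(gflat.sum(axis=0), own=True)
        if x.requires_grad:
            dcols = (gflat @ w.data.reshape(kernel * c_in, c_out).T).reshape(
                -1, length, kernel, c_in
            )
            dpad = np.zeros_like(padded)
            np.add.at(dpad, (slice(None), gather), dcols)
            dx = dpad[:, left:left + length, :].reshape(batch_shape + (length, c_in))
            dx = np.ascontiguousarray(dx[0] if squeeze else dx)
            x._accumulate(dx, own=True)

    out._backward = bwd
    return out


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy over a batch of logits (B, n_classes)."""
    logits = as_tensor(logits)
    labels = np.asarray(labels, dtype=np.intp)
    n = logits.shape[0]
    shifted = logits.data - logits.data.max(axis=1, keepdims=True)
    logz = np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    logp = shifted - logz
    out = Tensor(-logp[np.arange(n), labels].mean(), parents=(logits,))

    def bwd(g):
        soft = np.exp(logp)
        soft[np.arange(n), labels] -= 1.0
        logits._accumulate(g * soft / n, own=True)

    out._backward = bwd
    return out
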