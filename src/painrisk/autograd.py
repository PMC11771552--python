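"""Minimal reverse-mode automatic differentiation over numpy arrays.

The classifier in :mod:`painrisk.model` is small (tens of thousands of
parameters) and runs on a single CPU, so rather than depend on a deep-learning
framework the package carries its own tape-based autodiff: a :class:`Tensor`
wraps a float32 ``numpy`` array, records the operations applied to it, and
:meth:`Tensor.backward` accumulates gradients by walking the tape in reverse
topological order.

Only the operations the model needs are implemented (broadcast arithmetic,
batched ``matmul``, ``exp``/``log``/``relu``/``sigmoid``, axis reductions,
reshape/transpose/concatenate, embedding gather, clipping).  Gradients are
verified against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "masked_softmax_lastaxis",
    "set_default_dtype",
    "concat",
    "dropout",
    "embedding",
    "layer_norm",
    "softmax_lastaxis",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` back down to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # axes that were size 1 and got stretched
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


DEFAULT_DTYPE = np.float32


def set_default_dtype(dtype) -> None:
    """Switch the tape dtype (float32 by default; float64 for gradient checks)."""
    global DEFAULT_DTYPE
    DEFAULT_DTYPE = np.dtype(dtype).type


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(DEFAULT_DTYPE, copy=False)
    return np.asarray(x, dtype=DEFAULT_DTYPE)


class Tensor:
    """A numpy array with gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward_fn")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward_fn=None):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward_fn = backward_fn

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray, own: bool = False) -> None:
        # ``own=True`` promises ``g`` is a freshly allocated float32 array the
        # caller will not reuse, so it can be adopted without a copy.
        if self.grad is None:
            if own and g.dtype == DEFAULT_DTYPE and g.flags.writeable:
                self.grad = g
            else:
                self.grad = g.astype(DEFAULT_DTYPE, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (defaults to d(self)/d(self) = 1)."""
        if grad is None:
            grad = np.ones_like(self.data)
        self._accum(np.asarray(grad, dtype=DEFAULT_DTYPE))
        # iterative topological order over the tape
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        for node in reversed(order):
            if node._backward_fn is not None and node.grad is not None:
                node._backward_fn(node.grad)

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                ga = _unbroadcast(g, self.data.shape)
                self._accum(ga, own=ga is not g)
            if other.requires_grad or other._parents:
                gb = _unbroadcast(g, other.data.shape)
                other._accum(gb, own=gb is not g)

        out._backward_fn = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward_fn = lambda g: self._accum(-g, own=True)
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accum(_unbroadcast(g * other.data, self.data.shape), own=True)
            if other.requires_grad or other._parents:
                other._accum(_unbroadcast(g * self.data, other.data.shape), own=True)

        out._backward_fn = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accum(_unbroadcast(g / other.data, self.data.shape), own=True)
            if other.requires_grad or other._parents:
                other._accum(
                    _unbroadcast(-g * self.data / (other.data**2), other.data.shape),
                    own=True,
                )

        out._backward_fn = bw
        return out

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                ga = g @ other.data.swapaxes(-1, -2)
                self._accum(_unbroadcast(ga, self.data.shape), own=True)
            if other.requires_grad or other._parents:
                gb = self.data.swapaxes(-1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape), own=True)

        out._backward_fn = bw
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data**p, parents=(self,))
        out._backward_fn = lambda g: self._accum(g * p * self.data ** (p - 1), own=True)
        return out

    # ------------------------------------------------------------ elementwise
    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, parents=(self,))
        out._backward_fn = lambda g: self._accum(g * val, own=True)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward_fn = lambda g: self._accum(g / self.data, own=True)
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))
        out._backward_fn = lambda g: self._accum(g * mask, own=True)
        return out

    def sigmoid(self):
        val = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(val, parents=(self,))
        out._backward_fn = lambda g: self._accum(g * val * (1.0 - val), own=True)
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient is zero where the clamp is active."""
        inside = (self.data > lo) & (self.data < hi)
        out = Tensor(np.clip(self.data, lo, hi), parents=(self,))
        out._backward_fn = lambda g: self._accum(g * inside, own=True)
        return out

    # -------------------------------------------------------------- reduction
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        out._backward_fn = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------------ shape
    def reshape(self, *shape):
        orig = self.data.shape
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward_fn = lambda g: self._accum(g.reshape(orig))
        return out

    def transpose(self, *axes):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(*axes), parents=(self,))
        out._backward_fn = lambda g: self._accum(g.transpose(*inv))
        return out


# -------------------------------------------------------------- free functions
def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data, parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accum(g[tuple(sl)])

    out._backward_fn = bw
    return out


def embedding(table: Tensor, idx: np.ndarray) -> Tensor:
    """Row gather ``table[idx]`` with scatter-add gradient into the table."""
    out = Tensor(table.data[idx], parents=(table,))

    def bw(g):
        gt = np.zeros_like(table.data)
        np.add.at(gt, idx, g)
        table._accum(gt)

    out._backward_fn = bw
    return out


def softmax_lastaxis(x: Tensor) -> Tensor:
    """Numerically stable softmax along the last axis.

    The row max is treated as a constant: subtracting it does not change the
    softmax value and its gradient contributions cancel exactly.
    """
    shift = x - Tensor(x.data.max(axis=-1, keepdims=True))
    e = shift.exp()
    return e / e.sum(axis=-1, keepdims=True)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis with learnable gain and bias."""
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    return centered / ((var + eps) ** 0.5) * gain + bias


def dropout(
    x: Tensor,
    rate: float,
    rng: np.random.Generator | None,
    mask_shape: tuple[int, ...] | None = None,
) -> Tensor:
    """Inverted dropout; identity when ``rng`` is None (evaluation mode).

    ``mask_shape`` may be a broadcastable shape (e.g. sharing one mask across
    attention heads) to cut the cost of random-mask generation.
    """
    if rng is None or rate <= 0.0:
        return x
    u = rng.random(mask_shape or x.shape, dtype=np.float32)
    keep = (u >= rate).astype(x.data.dtype)
    keep /= 1.0 - rate
    return x * Tensor(keep)


def masked_softmax_lastaxis(scores: Tensor, key_mask: np.ndarray) -> Tensor:
    """Softmax over the last axis with masked entries fixed at exactly 0.

    ``key_mask`` broadcasts against ``scores``; True marks valid keys.  Rows
    with at least one valid key sum to 1; fully masked rows are all zeros.
    Implemented as one fused operation to avoid materializing the several
    large intermediates the composite formulation would create.
    """
    maskf = key_mask.astype(scores.data.dtype)
    # computed in place: the raw scores are not needed by any backward pass
    e = scores.data
    e -= e.max(axis=-1, keepdims=True)
    np.exp(e, out=e)
    e *= maskf
    denom = e.sum(axis=-1, keepdims=True)
    np.maximum(denom, np.float32(1e-30), out=denom)  # fully masked rows -> 0
    e /= denom
    probs = e
    out = Tensor(probs, parents=(scores,))

    def bw(g):
        inner = (g * probs).sum(axis=-1, keepdims=True)
        # g is this node's own accumulated gradient and is not read again
        # after this callback, so it can be consumed in place
        if not g.flags.writeable:
            g = g.copy()
        g -= inner
        g *= probs
        scores._accum(g, own=True)

    out._backward_fn = bw
    return out
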