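"""Minimal reverse-mode automatic differentiation on numpy arrays.

The graph attention model, its composite objective and the fine-tuning
head are all expressed with the small set of primitives defined here:
elementwise arithmetic, 2-D matrix products, row gathering, segment sums
and a numerically stable segment softmax.  Gradients propagate through a
topologically sorted tape; broadcasting is handled by summing gradients
over broadcast axes.  Every primitive is covered by finite-difference
tests.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "gather",
    "segment_sum",
    "segment_softmax",
    "dropout",
    "layer_norm",
    "batch_norm",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # Leading axes added by broadcasting.
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return Tensor._make(out_data, (self, other), backward)

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward(g):
            return (g * exponent * self.data ** (exponent - 1),)

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            return (g @ other.data.T, self.data.T @ g)

        return Tensor._make(out_data, (self, other), backward)

    # -- nonlinearities ------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def tanh(self):
        out_data = np.tanh(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * (1.0 - out_data**2),))

    def sigmoid(self):
        out_data = np.where(
            self.data >= 0,
            1.0 / (1.0 + np.exp(-np.clip(self.data, -700, 700))),
            np.exp(np.clip(self.data, -700, 700))
            / (1.0 + np.exp(np.clip(self.data, -700, 700))),
        )
        return Tensor._make(out_data, (self,), lambda g: (g * out_data * (1 - out_data),))

    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    def leaky_relu(self, slope: float = 0.2):
        factor = np.where(self.data > 0, 1.0, slope)
        return Tensor._make(self.data * factor, (self,), lambda g: (g * factor,))

    # -- reductions / shape --------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)
        return Tensor._make(out_data, (self,), lambda g: (g.reshape(self.shape),))

    def transpose(self):
        return Tensor._make(self.data.T, (self,), lambda g: (g.T,))

    # -- backprop ------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg


# -- free functions ------------------------------------------------------------


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        return tuple(
            np.take(g, np.arange(offsets[i], offsets[i + 1]), axis=axis)
            for i in range(len(tensors))
        )

    return Tensor._make(out_data, tensors, backward)


def gather(t: Tensor, index) -> Tensor:
    """Select rows of `t` (axis 0) by integer index, with repetition."""
    index = np.asarray(index, dtype=np.intp)
    out_data = t.data[index]

    def backward(g):
        grad = np.zeros_like(t.data)
        np.add.at(grad, index, g)
        return (grad,)

    return Tensor._make(out_data, (t,), backward)


def segment_sum(t: Tensor, segment_ids, num_segments: int) -> Tensor:
    """Sum rows of `t` into `num_segments` buckets given by `segment_ids`."""
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    out_data = np.zeros((num_segments,) + t.shape[1:], dtype=np.float64)
    np.add.at(out_data, segment_ids, t.data)

    def backward(g):
        return (g[segment_ids],)

    return Tensor._make(out_data, (t,), backward)


def segment_softmax(scores: Tensor, segment_ids, num_segments: int) -> Tensor:
    """Softmax of `scores` within each segment (rows sharing a segment id).

    Works on 1-D (E,) or 2-D (E, H) scores; normalization is along axis 0
    within each segment, independently per trailing column.  The per-segment
    max is subtracted as a constant for numerical stability, which leaves
    the gradient exact.
    """
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    maxes = np.full((num_segments,) + scores.shape[1:], -np.inf)
    np.maximum.at(maxes, segment_ids, scores.data)
    maxes[~np.isfinite(maxes)] = 0.0  # empty segments
    shifted = scores - Tensor(maxes[segment_ids])
    num = shifted.exp()
    denom = segment_sum(num, segment_ids, num_segments)
    return num / gather(denom, segment_ids)


def dropout(t: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return t
    mask = (rng.random(t.shape) >= p) / (1.0 - p)
    return t * Tensor(mask)


def layer_norm(t: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize each row over its features, then scale and shift."""
    mu = t.mean(axis=-1, keepdims=True)
    centered = t - mu
    var = (centered**2).mean(axis=-1, keepdims=True)
    return centered / (var + eps) ** 0.5 * gain + bias


def batch_norm(t: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize each feature over the batch (rows), then scale and shift.

    Batch statistics are used in both training and evaluation: the model is
    transductive and always sees the full node set, so there is no separate
    inference distribution to track running statistics for.
    """
    mu = t.mean(axis=0, keepdims=True)
    centered = t - mu
    var = (centered**2).mean(axis=0, keepdims=True)
    return centered / (var + eps) ** 0.5 * gain + bias


class Adam:
    """Adam optimizer with parameter groups and decoupled weight decay.

    Each group is ``{"params": {name: Tensor}, "lr": float, "weight_decay": float}``.
    """

    def __init__(self, groups, betas=(0.9, 0.999), eps: float = 1e-8):
        self.groups = []
        for g in groups:
            params = dict(g["params"])
            self.groups.append(
                {
                    "params": params,
                    "lr": g["lr"],
                    "weight_decay": g.get("weight_decay", 0.0),
                    "m": {k: np.zeros_like(p.data) for k, p in params.items()},
                    "v": {k: np.zeros_like(p.data) for k, p in params.items()},
                }
            )
        self.betas = betas
        self.eps = eps
        self.t = 0

    def zero_grad(self):
        for g in self.groups:
            for p in g["params"].values():
                p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for g in self.groups:
            lr, wd = g["lr"], g["weight_decay"]
            for k, p in g["params"].items():
                if p.grad is None:
                    continue
                grad = p.grad
                g["m"][k] = b1 * g["m"][k] + (1 - b1) * grad
                g["v"][k] = b2 * g["v"][k] + (1 - b2) * grad**2
                mhat = g["m"][k] / (1 - b1**self.t)
                vhat = g["v"][k] / (1 - b2**self.t)
                p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)
                if wd:
                    p.data -= lr * wd * p.data
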