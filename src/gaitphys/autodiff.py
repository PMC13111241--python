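"""Minimal reverse-mode automatic differentiation over numpy arrays.

The physics-constraint losses and the network are expressed as compositions of
the differentiable primitives defined here (element-wise arithmetic, matmul,
trigonometry, reductions, slicing, padding), so that constraint-violation
gradients propagate end-to-end to every upstream parameter.  The engine is
deliberately small: dynamic tape, topological-order backward, numpy broadcasting
semantics throughout.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concatenate",
    "stack",
    "softmax",
    "layer_norm",
    "dropout",
    "conv1d_causal",
    "AdamW",
    "clip_grad_norm",
    "cosine_lr",
    "numerical_grad",
]


_DTYPE = np.float64


def set_default_dtype(dtype) -> None:
    """Set the scalar type newly created tensors use.

    float64 (default) for numerical verification; float32 roughly halves
    training time at the model scales used here.
    """
    global _DTYPE
    if dtype not in (np.float32, np.float64):
        raise ValueError("dtype must be numpy float32 or float64")
    _DTYPE = dtype


def get_default_dtype():
    return _DTYPE


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with a gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = tuple(_parents)
        self._backward = _backward

    # ------------------------------------------------------------------ basics
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accum(self, g: np.ndarray, fresh: bool = False) -> None:
        """Accumulate a gradient contribution.

        ``fresh=True`` promises ``g`` is a newly allocated array that no other
        node aliases, letting us adopt it without a defensive copy.
        """
        if self.grad is None:
            if fresh and isinstance(g, np.ndarray) and g.base is None:
                self.grad = g
            else:
                self.grad = np.array(g, dtype=_DTYPE, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None, free_graph: bool = True) -> None:
        """Backpropagate; by default the tape is released afterwards.

        Releasing breaks the closure reference cycles between nodes and their
        backward functions, so intermediate activations and gradients are
        reclaimed immediately rather than at the next full GC pass.  Leaf
        tensors keep their accumulated ``grad``.
        """
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative DFS post-order (graphs can exceed recursion limits)
        while stack:
            node = stack.pop()
            if id(node) in seen:
                continue
            pending = [p for p in node._parents if id(p) not in seen and p.requires_grad]
            if pending:
                stack.append(node)
                stack.extend(pending)
            else:
                seen.add(id(node))
                topo.append(node)
        self._accum(np.asarray(grad, dtype=_DTYPE))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        if free_graph:
            for node in topo:
                if node._parents:  # interior node: drop tape entry and gradient
                    node._backward = None
                    node._parents = ()
                    node.grad = None

    def free_graph(self) -> None:
        """Release the tape below this tensor without backpropagating.

        For inference-only forward passes: breaks the closure cycles so large
        intermediate activations are reclaimed immediately.
        """
        stack = [self]
        seen: set[int] = set()
        while stack:
            node = stack.pop()
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.extend(node._parents)
            if node._parents:
                node._backward = None
                node._parents = ()

    # -------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def _bw(g):
            if self.requires_grad:
                ga = _unbroadcast(g, self.shape)
                self._accum(ga, fresh=ga is not g)
            if other.requires_grad:
                gb = _unbroadcast(g, other.shape)
                other._accum(gb, fresh=gb is not g)

        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def _bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape), fresh=True)
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape), fresh=True)

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def _bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape), fresh=True)
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.shape), fresh=True)

        out._backward = _bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, _parents=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1), fresh=True)

        out._backward = _bw
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(np.matmul(self.data, other.data), _parents=(self, other))

        def _bw(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.shape), fresh=True)
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.shape), fresh=True)

        out._backward = _bw
        return out

    # ------------------------------------------------------------ element-wise
    def _unary(self, fval, fgrad):
        out = Tensor(fval(self.data), _parents=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(g * fgrad(self.data, out.data), fresh=True)

        out._backward = _bw
        return out

    def exp(self):
        return self._unary(np.exp, lambda x, y: y)

    def log(self):
        return self._unary(np.log, lambda x, y: 1.0 / x)

    def sqrt(self):
        return self._unary(np.sqrt, lambda x, y: 0.5 / y)

    def sin(self):
        return self._unary(np.sin, lambda x, y: np.cos(x))

    def cos(self):
        return self._unary(np.cos, lambda x, y: -np.sin(x))

    def tanh(self):
        return self._unary(np.tanh, lambda x, y: 1.0 - y**2)

    def sigmoid(self):
        return self._unary(lambda x: 1.0 / (1.0 + np.exp(-x)), lambda x, y: y * (1.0 - y))

    def relu(self):
        return self._unary(lambda x: np.maximum(x, 0.0), lambda x, y: (x > 0).astype(float))

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def _bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy(), fresh=True)
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.shape).copy(), fresh=True)

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def amax(self, axis: int, keepdims: bool = False):
        """Maximum along one axis with subgradient routed to the arg-max."""
        idx = np.argmax(self.data, axis=axis)
        out_data = np.max(self.data, axis=axis, keepdims=keepdims)
        out = Tensor(out_data, _parents=(self,))

        def _bw(g):
            if not self.requires_grad:
                return
            gg = g if not keepdims else np.squeeze(g, axis=axis)
            grad = np.zeros_like(self.data)
            np.put_along_axis(
                grad, np.expand_dims(idx, axis), np.expand_dims(gg, axis), axis
            )
            self._accum(grad, fresh=True)

        out._backward = _bw
        return out

    # ------------------------------------------------------------ shape moves
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g.reshape(self.shape))
        return out

    def swapaxes(self, a: int, b: int):
        out = Tensor(np.swapaxes(self.data, a, b), _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(np.swapaxes(g, a, b))
        return out

    def transpose(self, axes):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _parents=(self,))

        def _bw(g):
            if not self.requires_grad:
                return
            grad = np.zeros_like(self.data)
            np.add.at(grad, idx, g)
            self._accum(grad, fresh=True)

        out._backward = _bw
        return out

    def pad_axis(self, axis: int, before: int, after: int):
        """Zero-pad along one axis (used for causal convolution)."""
        width = [(0, 0)] * self.ndim
        width[axis] = (before, after)
        out = Tensor(np.pad(self.data, width), _parents=(self,))
        sl = [slice(None)] * self.ndim
        sl[axis] = slice(before, before + self.shape[axis])
        sl = tuple(sl)
        out._backward = lambda g: self.requires_grad and self._accum(g[sl])
        return out

    def roll(self, shift: int, axis: int):
        out = Tensor(np.roll(self.data, shift, axis=axis), _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            np.roll(g, -shift, axis=axis)
        )
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def maximum(a, b) -> Tensor:
    """Element-wise max; at ties the gradient goes to the first argument."""
    a, b = as_tensor(a), as_tensor(b)
    take_a = a.data >= b.data
    out = Tensor(np.where(take_a, a.data, b.data), _parents=(a, b))

    def _bw(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * take_a, a.shape), fresh=True)
        if b.requires_grad:
            b._accum(_unbroadcast(g * ~take_a, b.shape), fresh=True)

    out._backward = _bw
    return out


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    out._backward = _bw
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), _parents=tuple(tensors))

    def _bw(g):
        parts = np.moveaxis(g, axis, 0)
        for t, gt in zip(tensors, parts):
            if t.requires_grad:
                t._accum(gt)

    out._backward = _bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(np.max(x.data, axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc**2).mean(axis=-1, keepdims=True)
    return xc / (var + eps).sqrt() * gain + bias


def dropout(x: Tensor, rate: float, rng: np.random.Generator, active: bool) -> Tensor:
    if not active or rate <= 0.0:
        return x
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask)


def conv1d_causal(x: Tensor, weight: Tensor, bias: Tensor, dilation: int = 1) -> Tensor:
    """Causal dilated 1-D convolution.

    ``x``: (..., T, C_in); ``weight``: (K, C_in, C_out); ``bias``: (C_out,).
    Output at time t sees inputs t, t-dilation, ..., t-(K-1)*dilation only.
    """
    k = weight.shape[0]
    t_len = x.shape[-2]
    xp = x.pad_axis(-2, (k - 1) * dilation, 0)
    terms = None
    for j in range(k):
        sl = [slice(None)] * x.ndim
        sl[-2] = slice(j * dilation, j * dilation + t_len)
        term = xp[tuple(sl)] @ weight[j]
        terms = term if terms is None else terms + term
    return terms + bias


# ------------------------------------------------------------------ optimizer
class AdamW:
    """Decoupled weight-decay Adam (Loshchilov & Hutter)."""

    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data)

    def state_dict(self):
        return {"t": self.t, "m": [m.copy() for m in self.m], "v": [v.copy() for v in self.v]}

    def load_state_dict(self, state):
        self.t = state["t"]
        self.m = [m.copy() for m in state["m"]]
        self.v = [v.copy() for v in state["v"]]


def clip_grad_norm(params, max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most ``max_norm``."""
    total = math.sqrt(sum(float((p.grad**2).sum()) for p in params if p.grad is not None))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return total


def cosine_lr(base_lr: float, epoch: int, total_epochs: int) -> float:
    return base_lr * 0.5 * (1.0 + math.cos(math.pi * min(epoch, total_epochs) / total_epochs))


def numerical_grad(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite-difference gradient of scalar ``f`` w.r.t. array ``x``."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f(x)
        x[i] = orig - eps
        fm = f(x)
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
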