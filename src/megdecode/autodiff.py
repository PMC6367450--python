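"""Reverse-mode automatic differentiation on numpy arrays.

This is the compute core of the package: a small tape-based autodiff engine
sufficient to express the spatial/temporal convolution stacks, recurrent
cells, soft attention, batch normalization and the losses used for training,
as well as gradients of model outputs with respect to their *inputs* (needed
for activation maximization).

Only the operations the package uses are implemented.  All arithmetic is
float64.  Gradients accumulate into ``Tensor.grad`` after ``backward()``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "stack", "SGD", "Adam"]


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
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _result(data, parents, backward):
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

    # -- autodiff --------------------------------------------------------------
    def backward(self, grad=None, retain_graph: bool = False):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed requires a scalar output")
            grad = np.ones_like(self.data)
        # iterative post-order topological sort (avoids recursion limits and
        # self-referencing closures that would defer graph teardown to the GC)
        topo, seen, stack = [], set(), [(self, False)]
        while stack:
            t, expanded = stack.pop()
            if not t.requires_grad or (id(t) in seen and not expanded):
                continue
            if expanded:
                topo.append(t)
                continue
            seen.add(id(t))
            stack.append((t, True))
            for p in t._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)
        if not retain_graph:
            for t in topo:
                if t._backward is not None:
                    t._backward = None
                    t._parents = ()
                    t.grad = None

    def _accum(self, g):
        if self.requires_grad:
            self.grad = g if self.grad is None else self.grad + g

    # -- arithmetic ------------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def bw(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._result(out_data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return Tensor._result(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._result(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def bw(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(_unbroadcast(-g * self.data / other.data**2, other.data.shape))

        return Tensor._result(out_data, (self, other), bw)

    def __pow__(self, p):
        assert np.isscalar(p)
        out_data = self.data**p

        def bw(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor._result(out_data, (self,), bw)

    # -- shaping ---------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out_data = self.data.reshape(shape)

        def bw(g):
            self._accum(g.reshape(old))

        return Tensor._result(out_data, (self,), bw)

    def transpose(self, axes):
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def bw(g):
            self._accum(g.transpose(inv))

        return Tensor._result(out_data, (self,), bw)

    def __getitem__(self, idx):
        out_data = self.data[idx]
        shape = self.data.shape

        def bw(g):
            gx = np.zeros(shape)
            np.add.at(gx, idx, g)
            self._accum(gx)

        return Tensor._result(out_data, (self,), bw)

    # -- reductions ------------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, shape).copy())

        return Tensor._result(out_data, (self,), bw)

    def max(self, axis: int):
        out_data = self.data.max(axis=axis)
        mask = self.data == np.expand_dims(out_data, axis)
        # ties share the incoming gradient equally
        mask = mask / mask.sum(axis=axis, keepdims=True)

        def bw(g):
            self._accum(np.expand_dims(g, axis) * mask)

        return Tensor._result(out_data, (self,), bw)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accum(g * out_data)

        return Tensor._result(out_data, (self,), bw)

    def log(self):
        out_data = np.log(self.data)

        def bw(g):
            self._accum(g / self.data)

        return Tensor._result(out_data, (self,), bw)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bw(g):
            self._accum(g * 0.5 / out_data)

        return Tensor._result(out_data, (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            self._accum(g * (1.0 - out_data**2))

        return Tensor._result(out_data, (self,), bw)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor._result(out_data, (self,), bw)

    def relu(self):
        mask = self.data > 0
        out_data = np.where(mask, self.data, 0.0)

        def bw(g):
            self._accum(g * mask)

        return Tensor._result(out_data, (self,), bw)

    def elu(self, alpha: float = 1.0):
        neg = np.exp(np.minimum(self.data, 0.0)) - 1.0
        out_data = np.where(self.data > 0, self.data, alpha * neg)

        def bw(g):
            self._accum(g * np.where(self.data > 0, 1.0, alpha * (neg + 1.0)))

        return Tensor._result(out_data, (self,), bw)

    def selu(self):
        # self-normalizing constants (Klambauer et al.)
        lam, alpha = 1.0507009873554805, 1.6732632423543772
        return self.elu(alpha) * lam

    # -- linear algebra --------------------------------------------------------
    def matmul(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data

        def bw(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        return Tensor._result(out_data, (self, other), bw)

    __matmul__ = matmul

    def contract(self, w, k: int):
        """tensordot: contract the last ``k`` axes of self with the first
        ``k`` axes of ``w``.  Output = self's leading axes + w's trailing axes."""
        w = as_tensor(w)
        out_data = np.tensordot(self.data, w.data, axes=k)
        n_batch = self.data.ndim - k
        j = w.data.ndim - k

        def bw(g):
            if j:
                ga = np.tensordot(
                    g, w.data, axes=(tuple(range(n_batch, n_batch + j)), tuple(range(k, k + j)))
                )
            else:
                ga = np.multiply.outer(g, w.data)
            self._accum(ga)
            gw = np.tensordot(self.data, g, axes=(tuple(range(n_batch)), tuple(range(n_batch))))
            w._accum(gw)

        return Tensor._result(out_data, (self, w), bw)

    def unfold(self, size: int, axis: int):
        """Sliding windows of ``size`` along ``axis``; window axis appended last."""
        out_data = np.lib.stride_tricks.sliding_window_view(
            self.data, window_shape=size, axis=axis
        ).copy()
        shape = self.data.shape
        n_out = shape[axis] - size + 1

        def bw(g):
            gx = np.zeros(shape)
            sl = [slice(None)] * len(shape)
            for k in range(size):
                sl[axis] = slice(k, k + n_out)
                gx[tuple(sl)] += g[..., k]
            self._accum(gx)

        return Tensor._result(out_data, (self,), bw)

    # -- composite helpers -----------------------------------------------------
    def softmax(self, axis: int = -1):
        shifted = self - np.max(self.data, axis=axis, keepdims=True)
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def log_softmax(self, axis: int = -1):
        shifted = self - np.max(self.data, axis=axis, keepdims=True)
        return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def bw(g):
        pieces = np.split(g, len(tensors), axis=axis)
        for t, piece in zip(tensors, pieces):
            t._accum(np.squeeze(piece, axis=axis))

    return Tensor._result(out_data, tuple(tensors), bw)


# ---------------------------------------------------------------------------
# Optimizers


class SGD:
    def __init__(self, params, lr: float = 0.01, momentum: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self._vel = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            v *= self.momentum
            v += p.grad
            p.data -= self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def step(self):
        self._t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            mh = m / (1 - self.b1**self._t)
            vh = v / (1 - self.b2**self._t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
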