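"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based engine: every operation builds a node that
remembers its parents and a closure accumulating gradients into them.
Only what the beat-classification network needs is implemented — elementwise
arithmetic with broadcasting, matmul, the usual activations, reductions,
shape ops, 1-D convolution via im2col, batch normalization, max pooling and
dropout.  Recurrent and spline layers define their own fused ops on top of
``Tensor.make`` (see ``network``), keeping the Python-level graph small.

Everything runs in float64: the gradient finite-difference checks in the
test suite rely on it, and at the widths this package trains at the cost is
negligible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "no_grad"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum out prepended axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were broadcast from size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class _NoGrad:
    _active = False

    def __enter__(self):
        self._prev = _NoGrad._active
        _NoGrad._active = True
        return self

    def __exit__(self, *exc):
        _NoGrad._active = self._prev
        return False


def no_grad() -> _NoGrad:
    """Context manager disabling graph construction (inference / updates)."""
    return _NoGrad()


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and not _NoGrad._active
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph construction -------------------------------------------------

    @staticmethod
    def make(data: np.ndarray, parents: tuple["Tensor", ...], backward) -> "Tensor":
        """Create a graph node. `backward(grad)` must accumulate into parents."""
        out = Tensor(data)
        if not _NoGrad._active and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; recursion depth explodes on long chains
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- conveniences -------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={'yes' if self.requires_grad else 'no'})"

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    # -- elementwise arithmetic --------------------------------------------

    def __add__(self, other):
        other = Tensor._wrap(other)
        out_data = self.data + other.data

        def backward(grad):
            if self.requires_grad:
                self._accum(_unbroadcast(grad, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(grad, other.data.shape))

        return Tensor.make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(grad):
            self._accum(-grad)

        return Tensor.make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        other = Tensor._wrap(other)
        out_data = self.data * other.data

        def backward(grad):
            if self.requires_grad:
                self._accum(_unbroadcast(grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(grad * self.data, other.data.shape))

        return Tensor.make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._wrap(other)
        out_data = self.data / other.data

        def backward(grad):
            if self.requires_grad:
                self._accum(_unbroadcast(grad / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-grad * self.data / other.data**2, other.data.shape))

        return Tensor.make(out_data, (self, other), backward)

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data**exponent

        def backward(grad):
            self._accum(grad * exponent * self.data ** (exponent - 1))

        return Tensor.make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = Tensor._wrap(other)
        out_data = self.data @ other.data

        def backward(grad):
            if self.requires_grad:
                self._accum(_unbroadcast(grad @ np.swapaxes(other.data, -1, -2), self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ grad, other.data.shape))

        return Tensor.make(out_data, (self, other), backward)

    # -- activations --------------------------------------------------------

    def relu(self):
        mask = self.data > 0

        def backward(grad):
            self._accum(grad * mask)

        return Tensor.make(self.data * mask, (self,), backward)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward(grad):
            self._accum(grad * s * (1.0 - s))

        return Tensor.make(s, (self,), backward)

    def tanh(self):
        t = np.tanh(self.data)

        def backward(grad):
            self._accum(grad * (1.0 - t * t))

        return Tensor.make(t, (self,), backward)

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out_data = self.data * s

        def backward(grad):
            self._accum(grad * (s + self.data * s * (1.0 - s)))

        return Tensor.make(out_data, (self,), backward)

    def exp(self):
        e = np.exp(self.data)

        def backward(grad):
            self._accum(grad * e)

        return Tensor.make(e, (self,), backward)

    def log(self):
        def backward(grad):
            self._accum(grad / self.data)

        return Tensor.make(np.log(self.data), (self,), backward)

    def clip_min(self, lo: float):
        """max(x, lo); gradient passes only where x > lo."""
        mask = self.data > lo

        def backward(grad):
            self._accum(grad * mask)

        return Tensor.make(np.maximum(self.data, lo), (self,), backward)

    # -- reductions and shape ops -------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(grad):
            g = grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor.make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        orig = self.data.shape

        def backward(grad):
            self._accum(grad.reshape(orig))

        return Tensor.make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def backward(grad):
            self._accum(grad.transpose(*inv))

        return Tensor.make(self.data.transpose(*axes), (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(grad):
            g = np.zeros_like(self.data)
            np.add.at(g, idx, grad)
            self._accum(g)

        return Tensor.make(out_data, (self,), backward)

    def gather_rows(self, index: np.ndarray):
        """out[i] = self[i, index[i]] for a 2-D tensor."""
        rows = np.arange(self.data.shape[0])
        out_data = self.data[rows, index]

        def backward(grad):
            g = np.zeros_like(self.data)
            np.add.at(g, (rows, index), grad)
            self._accum(g)

        return Tensor.make(out_data, (self,), backward)

    @staticmethod
    def concat(tensors: list["Tensor"], axis: int = 0) -> "Tensor":
        datas = [t.data for t in tensors]
        out_data = np.concatenate(datas, axis=axis)
        splits = np.cumsum([d.shape[axis] for d in datas])[:-1]

        def backward(grad):
            for t, g in zip(tensors, np.split(grad, splits, axis=axis)):
                if t.requires_grad:
                    t._accum(g)

        return Tensor.make(out_data, tuple(tensors), backward)

    # -- neural-net primitives ----------------------------------------------

    def conv1d(self, weight: "Tensor", bias: "Tensor | None" = None, padding: int = 0):
        """1-D cross-correlation. self: (N, C, L); weight: (O, C, K)."""
        x = self.data
        w = weight.data
        n, c, length = x.shape
        o, c2, k = w.shape
        if c != c2:
            raise ValueError(f"conv1d channel mismatch: input has {c}, weight expects {c2}")
        if length + 2 * padding < k:
            raise ValueError(f"conv1d input length {length} (+2*{padding} pad) shorter than kernel {k}")
        xp = np.pad(x, ((0, 0), (0, 0), (padding, padding))) if padding else x
        lout = length + 2 * padding - k + 1
        # shift-and-matmul over kernel taps: avoids materializing an
        # (N, C, Lout, K) im2col array, which dominates memory for wide kernels
        out = np.zeros((n, o, lout))
        for j in range(k):
            # (O, C) @ (N, C, Lout) -> (N, O, Lout), broadcast matmul
            out += np.matmul(w[:, :, j], xp[:, :, j : j + lout])
        if bias is not None:
            out += bias.data[None, :, None]

        parents = (self, weight) if bias is None else (self, weight, bias)

        def backward(grad):
            if weight.requires_grad:
                gw = np.empty_like(w)
                for j in range(k):
                    # contract (N, O, Lout) with (N, C, Lout) over n and l
                    gw[:, :, j] = np.tensordot(grad, xp[:, :, j : j + lout],
                                               axes=([0, 2], [0, 2]))
                weight._accum(gw)
            if bias is not None and bias.requires_grad:
                bias._accum(grad.sum(axis=(0, 2)))
            if self.requires_grad:
                gxp = np.zeros_like(xp)
                wt = w.transpose(1, 0, 2)  # (C, O, K)
                for j in range(k):
                    gxp[:, :, j : j + lout] += np.matmul(wt[:, :, j], grad)
                self._accum(gxp[:, :, padding : padding + length] if padding else gxp)

        return Tensor.make(out, parents, backward)

    def max_pool1d(self, kernel: int = 2, stride: int = 1, padding: int = 1):
        """Max pooling on (N, C, L). Padding uses -inf so it never wins."""
        x = self.data
        n, c, length = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (padding, padding)), constant_values=-np.inf) if padding else x
        lout = (xp.shape[2] - kernel) // stride + 1
        taps = [xp[:, :, j : j + stride * lout : stride] for j in range(kernel)]
        out = taps[0]
        for t in taps[1:]:
            out = np.maximum(out, t)

        def backward(grad):
            gxp = np.zeros((n, c, length + 2 * padding))
            credited = np.zeros(out.shape, dtype=bool)  # first max wins ties
            for j in range(kernel):
                hit = (taps[j] == out) & ~credited
                credited |= hit
                gxp[:, :, j : j + stride * lout : stride] += grad * hit
            self._accum(gxp[:, :, padding : padding + length] if padding else gxp)

        return Tensor.make(out, (self,), backward)

    def batch_norm(self, gamma: "Tensor", beta: "Tensor", running_mean: np.ndarray,
                   running_var: np.ndarray, training: bool, momentum: float = 0.1,
                   eps: float = 1e-5):
        """BatchNorm1d over (N, C, L) or (N, C); running stats updated in place."""
        x = self.data
        axes = (0, 2) if x.ndim == 3 else (0,)
        shape = (1, -1, 1) if x.ndim == 3 else (1, -1)
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = x.size // x.shape[1]
            running_mean *= 1.0 - momentum
            running_mean += momentum * mu
            running_var *= 1.0 - momentum
            # unbiased estimate feeds the running average, as is conventional
            running_var += momentum * (var * m / max(m - 1, 1))
        else:
            mu, var = running_mean, running_var
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x - mu.reshape(shape)) * inv.reshape(shape)
        out = gamma.data.reshape(shape) * xhat + beta.data.reshape(shape)

        def backward(grad):
            if gamma.requires_grad:
                gamma._accum((grad * xhat).sum(axis=axes))
            if beta.requires_grad:
                beta._accum(grad.sum(axis=axes))
            if self.requires_grad:
                g = grad * gamma.data.reshape(shape)
                if training:
                    m = x.size // x.shape[1]
                    gx = (
                        g
                        - g.mean(axis=axes, keepdims=True)
                        - xhat * (g * xhat).mean(axis=axes, keepdims=True)
                    ) * inv.reshape(shape)
                else:
                    gx = g * inv.reshape(shape)
                self._accum(gx)

        return Tensor.make(out, (self, gamma, beta), backward)

    def dropout(self, p: float, rng: np.random.Generator, training: bool):
        if not training or p <= 0.0:
            return self
        mask = (rng.random(self.data.shape) >= p) / (1.0 - p)

        def backward(grad):
            self._accum(grad * mask)

        return Tensor.make(self.data * mask, (self,), backward)

    def softmax(self, axis: int = -1):
        """Numerically stable softmax along `axis` (shift by a detached max)."""
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)
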