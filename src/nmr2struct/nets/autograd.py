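"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This is the package's own NN engine: a tape-based autograd supporting the
operations the transformer and CNN frontends need (broadcasted arithmetic,
batched matmul, softmax, layer norm, embedding gather, strided 1D
convolution, masked cross-entropy).  Arrays are float32 throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "concat", "embedding", "layer_norm",
           "conv1d", "cross_entropy_masked", "dropout", "no_grad"]

_GRAD_ENABLED = [True]


class no_grad:
    """Context manager disabling graph construction (inference only)."""

    def __enter__(self):
        self._prev = _GRAD_ENABLED[0]
        _GRAD_ENABLED[0] = False
        return self

    def __exit__(self, *exc):
        _GRAD_ENABLED[0] = self._prev
        return False


def _tune_allocator():
    # Training allocates and frees many multi-MB graph intermediates per step;
    # with glibc defaults these cross the dynamic mmap threshold and every step
    # pays full page-fault cost. Raising the thresholds keeps freed blocks
    # in-process. No-op on non-glibc platforms.
    try:
        import ctypes

        libc = ctypes.CDLL("libc.so.6", use_errno=True)
        M_TRIM_THRESHOLD, M_MMAP_THRESHOLD = -1, -3
        libc.mallopt(M_TRIM_THRESHOLD, 1 << 30)
        libc.mallopt(M_MMAP_THRESHOLD, 1 << 30)
    except Exception:
        pass


_tune_allocator()


class Tensor:
    """A NumPy array with an attached gradient and backward closure."""

    __slots__ = ("data", "grad", "_backward", "_parents", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        if _GRAD_ENABLED[0]:
            self._parents = parents
            self._backward = backward
            self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        else:
            self._parents = ()
            self._backward = None
            self.requires_grad = False

    # -- graph machinery -----------------------------------------------------

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited or not node.requires_grad:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad):
        # accumulation is not in-place: the incoming array may be shared
        # with another consumer's backward closure
        if self.grad is None:
            self.grad = np.asarray(grad, dtype=np.float32)
        else:
            self.grad = self.grad + grad

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    # -- operations -----------------------------------------------------------

    def __add__(self, other):
        other = _wrap(other)
        out = Tensor(self.data + other.data, (self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-_wrap(other))

    def __rsub__(self, other):
        return _wrap(other) + (-self)

    def __mul__(self, other):
        other = _wrap(other)
        out = Tensor(self.data * other.data, (self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = _wrap(other)
        out = Tensor(self.data / other.data, (self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = _wrap(other)
        out = Tensor(np.matmul(self.data, other.data), (self, other))

        def backward(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                if other.data.ndim == 2 and self.data.ndim > 2:
                    # (..., m, k) @ (k, n): fold leading dims into one GEMM
                    k = self.data.shape[-1]
                    n = g.shape[-1]
                    gb = self.data.reshape(-1, k).T @ g.reshape(-1, n)
                else:
                    gb = _unbroadcast(
                        np.matmul(np.swapaxes(self.data, -1, -2), g), other.data.shape
                    )
                other._accum(gb)

        out._backward = backward
        return out

    def reshape(self, *shape):
        orig = self.data.shape
        out = Tensor(self.data.reshape(*shape), (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g.reshape(orig))
        return out

    def transpose(self, *axes):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(*axes), (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g.transpose(*inv))
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def backward(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * mask)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * s * (1 - s))
        return out

    def log(self):
        out = Tensor(np.log(self.data), (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g / self.data)
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through only in the interior."""
        mask = (self.data > lo) & (self.data < hi)
        out = Tensor(np.clip(self.data, lo, hi), (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * mask)
        return out

    def softmax(self, axis=-1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, (self,))

        def backward(g):
            if self.requires_grad:
                dot = (g * s).sum(axis=axis, keepdims=True)
                self._accum(s * (g - dot))

        out._backward = backward
        return out

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={'set' if self.grad is not None else 'none'})"


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to produce ``grad.shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# --- fused / specialized operations ----------------------------------------


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    out._backward = backward
    return out


def embedding(weight: Tensor, indices: np.ndarray) -> Tensor:
    """Row-gather ``weight[indices]`` with scatter-add backward."""
    idx = np.asarray(indices, dtype=np.int64)
    out = Tensor(weight.data[idx], (weight,))

    def backward(g):
        if weight.requires_grad:
            acc = np.zeros_like(weight.data)
            np.add.at(acc, idx.ravel(), g.reshape(-1, weight.data.shape[-1]))
            weight._accum(acc)

    out._backward = backward
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = Tensor(xhat * gamma.data + beta.data, (x, gamma, beta))
    d = x.data.shape[-1]

    def backward(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=tuple(range(g.ndim - 1))))
        if beta.requires_grad:
            beta._accum(g.sum(axis=tuple(range(g.ndim - 1))))
        if x.requires_grad:
            gx = g * gamma.data
            term1 = gx
            term2 = gx.mean(axis=-1, keepdims=True)
            term3 = xhat * (gx * xhat).mean(axis=-1, keepdims=True)
            x._accum(inv * (term1 - term2 - term3))

    out._backward = backward
    return out


def conv1d(x: Tensor, weight: Tensor, bias: Tensor, stride: int) -> Tensor:
    """1D convolution, channels-last: x (B, L, C_in), weight (k*C_in, C_out).

    The kernel size is inferred from the weight shape.  Output length is
    ``(L - k) // stride + 1``.
    """
    B, L, C = x.data.shape
    k = weight.data.shape[0] // C
    windows = np.lib.stride_tricks.sliding_window_view(x.data, k, axis=1)[:, ::stride]
    # windows: (B, Lout, C, k) -> (B, Lout, k*C)
    cols = windows.transpose(0, 1, 3, 2).reshape(B, -1, k * C)
    Lout = cols.shape[1]
    y = np.matmul(cols, weight.data) + bias.data
    out = Tensor(y, (x, weight, bias))
    starts = np.arange(Lout) * stride

    def backward(g):
        if bias.requires_grad:
            bias._accum(g.sum(axis=(0, 1)))
        if weight.requires_grad:
            gw = np.einsum("blc,blo->co", cols, g)
            weight._accum(gw)
        if x.requires_grad:
            gcols = np.matmul(g, weight.data.T).reshape(B, Lout, k, C)
            gx = np.zeros_like(x.data)
            for j in range(k):
                np.add.at(gx, (slice(None), starts + j), gcols[:, :, j])
            x._accum(gx)

    out._backward = backward
    return out


def cross_entropy_masked(
    logits: Tensor, targets: np.ndarray, mask: np.ndarray
) -> Tensor:
    """Mean token-level cross-entropy over positions where ``mask`` is true.

    ``logits`` has shape (B, T, A); ``targets`` (B, T) int; ``mask`` (B, T).
    """
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    logp = z - logsumexp
    B, T, A = logits.data.shape
    tgt = np.asarray(targets, dtype=np.int64)
    m = np.asarray(mask, dtype=np.float32)
    n = max(m.sum(), 1.0)
    picked = np.take_along_axis(logp, tgt[..., None], axis=-1)[..., 0]
    loss = -(picked * m).sum() / n
    out = Tensor(loss, (logits,))

    def backward(g):
        if logits.requires_grad:
            p = np.exp(logp)
            onehot = np.zeros_like(p)
            np.put_along_axis(onehot, tgt[..., None], 1.0, axis=-1)
            logits._accum(g * (p - onehot) * m[..., None] / n)

    out._backward = backward
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0:
        return x
    keep = (rng.random(x.data.shape) >= p).astype(np.float32) / (1.0 - p)
    out = Tensor(x.data * keep, (x,))
    out._backward = lambda g: x.requires_grad and x._accum(g * keep)
    return out
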