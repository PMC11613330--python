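"""NN building blocks: modules, attention, transformer layers, CNN blocks.

Transformer layers use the pre-norm arrangement (layer norm before each
sublayer) which trains stably at small scale without a warmup schedule.
Attention masks are additive: 0 at attendable positions, a large negative
number at masked positions.
"""

from __future__ import annotations

import numpy as np

from .autograd import (
    Parameter,
    Tensor,
    concat,
    conv1d,
    dropout,
    embedding,
    layer_norm,
)

NEG_INF = -1e9


class Module:
    """Base class: tracks parameters and submodules through attribute assignment."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", False)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        elif isinstance(value, ModuleList):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> dict[str, Parameter]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, mod in self._modules.items():
            out.update(mod.named_parameters(prefix=f"{prefix}{name}."))
        return out

    def parameters(self) -> list[Parameter]:
        return list(self.named_parameters().values())

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = self.named_parameters()
        missing = set(params) - set(state)
        extra = set(state) - set(params)
        if missing or extra:
            raise ValueError(f"state mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}: {p.data.shape} vs {state[k].shape}")
            p.data = state[k].astype(np.float32).copy()
        return self


class ModuleList(Module):
    def __init__(self, modules):
        super().__init__()
        self._list = list(modules)
        for i, m in enumerate(self._list):
            self._modules[str(i)] = m

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape or (fan_in, fan_out)).astype(np.float32)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(_xavier(rng, d_in, d_out))
        self.bias = Parameter(np.zeros(d_out, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        if x.ndim > 2:
            # fold leading dims so the product is a single GEMM
            shape = x.shape
            y = x.reshape(-1, shape[-1]) @ self.weight + self.bias
            return y.reshape(*shape[:-1], self.weight.shape[1])
        return x @ self.weight + self.bias


class Embedding(Module):
    def __init__(self, n: int, d: int, rng: np.random.Generator, pad_zero: bool = False):
        super().__init__()
        w = (rng.standard_normal((n, d)) * 0.02).astype(np.float32)
        if pad_zero:
            w[0] = 0.0
        self.weight = Parameter(w)

    def __call__(self, idx: np.ndarray) -> Tensor:
        return embedding(self.weight, idx)


class LayerNorm(Module):
    def __init__(self, d: int):
        super().__init__()
        self.gamma = Parameter(np.ones(d, dtype=np.float32))
        self.beta = Parameter(np.zeros(d, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta)


def sinusoidal_positions(length: int, d: int) -> np.ndarray:
    """Standard sin/cos positional encoding table, shape (length, d)."""
    pos = np.arange(length)[:, None]
    i = np.arange(d)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d)
    table = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return table.astype(np.float32)


class MultiHeadAttention(Module):
    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)

    def _split(self, x: Tensor) -> Tensor:
        B, L, D = x.shape
        return x.reshape(B, L, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def __call__(self, q: Tensor, k: Tensor, v: Tensor, mask: np.ndarray | None = None) -> Tensor:
        """mask: additive, broadcastable to (B, heads, Lq, Lk)."""
        B, Lq, D = q.shape
        qh, kh, vh = self._split(self.wq(q)), self._split(self.wk(k)), self._split(self.wv(v))
        scores = (qh @ kh.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.d_head))
        if mask is not None:
            scores = scores + mask.astype(np.float32)
        attn = scores.softmax(axis=-1)
        ctx = attn @ vh
        ctx = ctx.transpose(0, 2, 1, 3).reshape(B, Lq, D)
        return self.wo(ctx)


class FeedForward(Module):
    def __init__(self, d_model: int, d_ff: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(d_model, d_ff, rng)
        self.fc2 = Linear(d_ff, d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class EncoderLayer(Module):
    def __init__(self, d_model: int, n_heads: int, d_ff: int, p_drop: float, rng):
        super().__init__()
        self.ln1 = LayerNorm(d_model)
        self.attn = MultiHeadAttention(d_model, n_heads, rng)
        self.ln2 = LayerNorm(d_model)
        self.ff = FeedForward(d_model, d_ff, rng)
        self.p_drop = p_drop

    def __call__(self, x: Tensor, mask, rng) -> Tensor:
        h = self.ln1(x)
        x = x + dropout(self.attn(h, h, h, mask), self.p_drop, rng, self.training)
        x = x + dropout(self.ff(self.ln2(x)), self.p_drop, rng, self.training)
        return x


class DecoderLayer(Module):
    def __init__(self, d_model: int, n_heads: int, d_ff: int, p_drop: float, rng):
        super().__init__()
        self.ln1 = LayerNorm(d_model)
        self.self_attn = MultiHeadAttention(d_model, n_heads, rng)
        self.ln2 = LayerNorm(d_model)
        self.cross_attn = MultiHeadAttention(d_model, n_heads, rng)
        self.ln3 = LayerNorm(d_model)
        self.ff = FeedForward(d_model, d_ff, rng)
        self.p_drop = p_drop

    def __call__(self, x: Tensor, memory: Tensor, self_mask, cross_mask, rng) -> Tensor:
        h = self.ln1(x)
        x = x + dropout(self.self_attn(h, h, h, self_mask), self.p_drop, rng, self.training)
        h = self.ln2(x)
        x = x + dropout(self.cross_attn(h, memory, memory, cross_mask), self.p_drop, rng, self.training)
        x = x + dropout(self.ff(self.ln3(x)), self.p_drop, rng, self.training)
        return x


class ConvBlock(Module):
    """Strided 1D convolution + ReLU (channels-last)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int, rng):
        super().__init__()
        self.kernel = kernel
        self.stride = stride
        self.weight = Parameter(_xavier(rng, kernel * c_in, c_out))
        self.bias = Parameter(np.zeros(c_out, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, self.stride).relu()


def causal_mask(length: int) -> np.ndarray:
    """Additive mask forbidding attention to future positions; shape (1,1,L,L)."""
    m = np.triu(np.full((length, length), NEG_INF, dtype=np.float32), k=1)
    return m[None, None]


def padding_mask(pad: np.ndarray) -> np.ndarray:
    """Additive key-padding mask from a boolean (B, L) pad indicator; (B,1,1,L)."""
    return np.where(pad, NEG_INF, 0.0).astype(np.float32)[:, None, None, :]
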