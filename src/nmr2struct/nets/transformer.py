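"""The substructure-to-structure encoder-decoder transformer.

The encoder consumes compact presence-index sequences (1-based indices of
the set fingerprint bits, 0 = padding) embedded without positional
encoding — the indices describe a set, not a sequence.  The decoder emits
SMILES token logits autoregressively, conditioned on the encoder memory
through cross-attention, with sinusoidal positional encoding and a causal
mask.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .autograd import Tensor
from .layers import (
    DecoderLayer,
    Embedding,
    EncoderLayer,
    LayerNorm,
    Linear,
    Module,
    ModuleList,
    causal_mask,
    padding_mask,
    sinusoidal_positions,
)

__all__ = ["TransformerConfig", "Substruct2Struct", "build_substruct2struct",
           "IncrementalDecoder"]


@dataclass(frozen=True)
class TransformerConfig:
    """Architecture of the encoder-decoder transformer.

    ``vocab_size`` is the substructure vocabulary size V (source side);
    ``alphabet_size`` the SMILES token alphabet size (target side).
    The desk-scale defaults are far smaller than a production
    configuration and are documented as such.
    """

    d_model: int = 64
    n_heads: int = 4
    n_encoder_layers: int = 2
    n_decoder_layers: int = 2
    d_ff: int = 128
    dropout: float = 0.0
    max_src_len: int = 64
    max_tgt_len: int = 64
    alphabet_size: int = 32
    vocab_size: int = 20

    def __post_init__(self):
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        for field_name in ("d_model", "n_heads", "n_encoder_layers", "n_decoder_layers",
                           "d_ff", "max_src_len", "max_tgt_len", "alphabet_size", "vocab_size"):
            if getattr(self, field_name) <= 0:
                raise ValueError(f"{field_name} must be positive")


class _Seq2SeqBase(Module):
    """Shared decoder-side machinery: token embedding, decoder stack, projection.

    Attribute names are part of the weight-transfer contract between the
    substructure-to-structure model and the multitask model.
    """

    def __init__(self, cfg: TransformerConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        d = cfg.d_model
        self.token_embedding = Embedding(cfg.alphabet_size, d, rng)
        self.encoder_layers = ModuleList(
            [EncoderLayer(d, cfg.n_heads, cfg.d_ff, cfg.dropout, rng)
             for _ in range(cfg.n_encoder_layers)]
        )
        self.encoder_norm = LayerNorm(d)
        self.decoder_layers = ModuleList(
            [DecoderLayer(d, cfg.n_heads, cfg.d_ff, cfg.dropout, rng)
             for _ in range(cfg.n_decoder_layers)]
        )
        self.decoder_norm = LayerNorm(d)
        self.out_proj = Linear(d, cfg.alphabet_size, rng)
        self._pos = sinusoidal_positions(cfg.max_tgt_len + 2, d)
        self._drop_rng = np.random.default_rng(0)

    def reseed_dropout(self, seed: int):
        self._drop_rng = np.random.default_rng(seed)

    def _run_encoder(self, x: Tensor, mask) -> Tensor:
        for layer in self.encoder_layers:
            x = layer(x, mask, self._drop_rng)
        return self.encoder_norm(x)

    def decode(self, memory: Tensor, src_pad: np.ndarray | None, tgt_in: np.ndarray) -> Tensor:
        """Teacher-forced decoder logits, shape (B, T, alphabet_size)."""
        tgt_in = np.asarray(tgt_in, dtype=np.int64)
        B, T = tgt_in.shape
        x = self.token_embedding(tgt_in) + self._pos[:T]
        self_mask = causal_mask(T) + padding_mask(tgt_in == 0)
        cross_mask = padding_mask(src_pad) if src_pad is not None else None
        for layer in self.decoder_layers:
            x = layer(x, memory, self_mask, cross_mask, self._drop_rng)
        return self.out_proj(self.decoder_norm(x))


class IncrementalDecoder:
    """Plain-NumPy autoregressive decoding with per-layer key/value caches.

    Numerically equivalent to :meth:`_Seq2SeqBase.decode` restricted to the
    last position (verified in the test suite), but each step costs O(1)
    decoder passes instead of re-running the whole prefix.  Inference only —
    no gradient graph is built.
    """

    _EPS = 1e-5  # must match autograd.layer_norm

    def __init__(self, model: "_Seq2SeqBase", memory: np.ndarray,
                 src_pad: np.ndarray | None):
        self.model = model
        self.memory = np.asarray(memory, dtype=np.float32)
        B = self.memory.shape[0]
        self.t = 0
        self.layers = []
        cross_bias = (
            np.where(src_pad, -1e9, 0.0).astype(np.float32)[:, None, None, :]
            if src_pad is not None else None
        )
        for layer in model.decoder_layers:
            h = layer.cross_attn.n_heads
            dh = layer.cross_attn.d_head
            mk = self._linear(self.memory, layer.cross_attn.wk)
            mv = self._linear(self.memory, layer.cross_attn.wv)
            self.layers.append({
                "layer": layer,
                "cross_k": self._heads(mk, h, dh),
                "cross_v": self._heads(mv, h, dh),
                "cross_bias": cross_bias,
                "self_k": np.zeros((B, h, 0, dh), dtype=np.float32),
                "self_v": np.zeros((B, h, 0, dh), dtype=np.float32),
            })

    @staticmethod
    def _linear(x: np.ndarray, lin) -> np.ndarray:
        return x @ lin.weight.data + lin.bias.data

    @staticmethod
    def _heads(x: np.ndarray, h: int, dh: int) -> np.ndarray:
        B, L, _ = x.shape
        return x.reshape(B, L, h, dh).transpose(0, 2, 1, 3)

    @classmethod
    def _layer_norm(cls, x: np.ndarray, ln) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        return (x - mu) / np.sqrt(var + cls._EPS) * ln.gamma.data + ln.beta.data

    def _attend(self, q: np.ndarray, k: np.ndarray, v: np.ndarray, attn,
                bias: np.ndarray | None) -> np.ndarray:
        # q: (B, heads, 1, dh); k, v: (B, heads, L, dh)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(attn.d_head))
        if bias is not None:
            scores = scores + bias
        scores -= scores.max(axis=-1, keepdims=True)
        p = np.exp(scores)
        p /= p.sum(axis=-1, keepdims=True)
        ctx = p @ v  # (B, heads, 1, dh)
        B = ctx.shape[0]
        ctx = ctx.transpose(0, 2, 1, 3).reshape(B, 1, -1)
        return self._linear(ctx, attn.wo)

    def step(self, tokens: np.ndarray) -> np.ndarray:
        """Advance one position; returns next-token logits, shape (B, A)."""
        m = self.model
        x = m.token_embedding.weight.data[np.asarray(tokens, dtype=np.int64)]
        x = (x + m._pos[self.t])[:, None, :]  # (B, 1, d)
        for entry in self.layers:
            layer = entry["layer"]
            h = self._layer_norm(x, layer.ln1)
            attn = layer.self_attn
            qh = self._heads(self._linear(h, attn.wq), attn.n_heads, attn.d_head)
            kh = self._heads(self._linear(h, attn.wk), attn.n_heads, attn.d_head)
            vh = self._heads(self._linear(h, attn.wv), attn.n_heads, attn.d_head)
            entry["self_k"] = np.concatenate([entry["self_k"], kh], axis=2)
            entry["self_v"] = np.concatenate([entry["self_v"], vh], axis=2)
            x = x + self._attend(qh, entry["self_k"], entry["self_v"], attn, None)
            h = self._layer_norm(x, layer.ln2)
            attn = layer.cross_attn
            qh = self._heads(self._linear(h, attn.wq), attn.n_heads, attn.d_head)
            x = x + self._attend(qh, entry["cross_k"], entry["cross_v"], attn,
                                 entry["cross_bias"])
            h = self._layer_norm(x, layer.ln3)
            h = np.maximum(self._linear(h, layer.ff.fc1), 0.0)
            x = x + self._linear(h, layer.ff.fc2)
        self.t += 1
        out = self._layer_norm(x, self.model.decoder_norm)
        return self._linear(out, self.model.out_proj)[:, 0, :]


class Substruct2Struct(_Seq2SeqBase):
    """Encoder-decoder transformer mapping presence indices to SMILES tokens."""

    def __init__(self, cfg: TransformerConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        super().__init__(cfg, rng)
        # index 0 is padding; indices 1..V are substructures
        self.substruct_embedding = Embedding(cfg.vocab_size + 1, cfg.d_model, rng, pad_zero=True)
        self.seed = seed

    def encode(self, src: np.ndarray) -> tuple[Tensor, np.ndarray]:
        """Encode padded presence-index sequences (B, S) → memory, pad indicator."""
        src = np.asarray(src, dtype=np.int64)
        pad = src == 0
        x = self.substruct_embedding(src)  # no positional encoding: set semantics
        memory = self._run_encoder(x, padding_mask(pad))
        return memory, pad

    def forward(self, src: np.ndarray, tgt_in: np.ndarray) -> Tensor:
        memory, pad = self.encode(src)
        return self.decode(memory, pad, tgt_in)

    __call__ = forward


def build_substruct2struct(config: TransformerConfig, seed: int = 0) -> Substruct2Struct:
    """Construct a substructure-to-structure model with seeded initialization."""
    return Substruct2Struct(config, seed=seed)
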