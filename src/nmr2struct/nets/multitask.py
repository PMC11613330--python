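"""The multitask spectrum-to-structure / spectrum-to-substructure model.

The processed ^1H spectrum (28000 values) passes through a strided 1D CNN
that downsamples it into a short sequence of feature vectors; the binned
^13C indicator embeds each of its bins into a dense vector (a learned
per-bin position tag plus a value-gated content embedding, so only set
bins contribute content).  With both modalities the two feature sequences
are concatenated along the sequence axis; a single-modality model retains
only its own path.  The shared encoder and the SMILES decoder have exactly
the shapes of the substructure-to-structure transformer so pretrained
weights can be transferred; the substructure head is a fresh transformer
encoder ending in per-substructure sigmoid probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, Parameter
from .layers import ConvBlock, EncoderLayer, LayerNorm, Linear, Module, ModuleList
from .transformer import TransformerConfig, _Seq2SeqBase

__all__ = ["MultitaskConfig", "Multitask", "build_multitask", "transfer_weights", "TransferError"]

MODALITIES = ("h1", "c13", "both")


@dataclass(frozen=True)
class MultitaskConfig:
    """Transformer core + spectral frontend specification.

    ``lam`` weights the substructure loss in the joint objective
    (total = structure + lam · substructure).
    """

    transformer: TransformerConfig = field(default_factory=TransformerConfig)
    cnn_channels: tuple[int, ...] = (16, 32, 64)
    cnn_kernels: tuple[int, ...] = (10, 6, 6)
    cnn_strides: tuple[int, ...] = (10, 6, 6)
    h1_length: int = 28000
    n_bins_13c: int = 80
    modality: str = "both"
    lam: float = 1.0
    n_substruct_layers: int = 1

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")
        if not (len(self.cnn_channels) == len(self.cnn_kernels) == len(self.cnn_strides)):
            raise ValueError("CNN channel/kernel/stride specs must have equal length")
        if self.lam < 0:
            raise ValueError("lam must be non-negative")

    @property
    def h1_feature_length(self) -> int:
        length = self.h1_length
        for k, s in zip(self.cnn_kernels, self.cnn_strides):
            length = (length - k) // s + 1
        return length

    @property
    def feature_length(self) -> int:
        n = 0
        if self.modality in ("h1", "both"):
            n += self.h1_feature_length
        if self.modality in ("c13", "both"):
            n += self.n_bins_13c
        return n


class Multitask(_Seq2SeqBase):
    """Joint spectrum-to-structure (SMILES) and spectrum-to-substructure model."""

    def __init__(self, cfg: MultitaskConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        super().__init__(cfg.transformer, rng)
        self.mcfg = cfg
        d = cfg.transformer.d_model
        if cfg.modality in ("h1", "both"):
            chans = (1,) + cfg.cnn_channels
            self.cnn = ModuleList(
                [ConvBlock(chans[i], chans[i + 1], cfg.cnn_kernels[i], cfg.cnn_strides[i], rng)
                 for i in range(len(cfg.cnn_channels))]
            )
            self.h1_proj = Linear(cfg.cnn_channels[-1], d, rng)
            # the encoder itself is position-free (set semantics for
            # substructure profiles), so the ppm axis must be injected
            # here: one learned position vector per CNN output position,
            # mirroring the per-bin position vectors of the 13C branch
            self.h1_pos = Parameter(
                (rng.standard_normal((cfg.h1_feature_length, d)) * 0.02).astype(np.float32)
            )
        if cfg.modality in ("c13", "both"):
            self.c13_pos = Parameter((rng.standard_normal((cfg.n_bins_13c, d)) * 0.02).astype(np.float32))
            self.c13_val = Parameter((rng.standard_normal((cfg.n_bins_13c, d)) * 0.02).astype(np.float32))
        self.substruct_layers = ModuleList(
            [EncoderLayer(d, cfg.transformer.n_heads, cfg.transformer.d_ff, cfg.transformer.dropout, rng)
             for _ in range(cfg.n_substruct_layers)]
        )
        self.substruct_norm = LayerNorm(d)
        self.substruct_proj = Linear(d, cfg.transformer.vocab_size, rng)
        self.seed = seed

    # -- feature extraction ---------------------------------------------------

    def _check_inputs(self, h1, c13):
        mode = self.mcfg.modality
        if mode == "h1":
            if c13 is not None:
                raise ValueError("modality='h1' model does not accept a 13C input")
            if h1 is None:
                raise ValueError("modality='h1' model requires a 1H input")
        elif mode == "c13":
            if h1 is not None:
                raise ValueError("modality='c13' model does not accept a 1H input")
            if c13 is None:
                raise ValueError("modality='c13' model requires a 13C input")
        else:
            if h1 is None or c13 is None:
                raise ValueError("modality='both' model requires 1H and 13C inputs")

    def features(self, h1: np.ndarray | None, c13: np.ndarray | None) -> Tensor:
        """Spectral feature sequence (B, L_feat, d_model)."""
        self._check_inputs(h1, c13)
        parts: list[Tensor] = []
        if h1 is not None:
            x = Tensor(np.asarray(h1, dtype=np.float32)[:, :, None])
            for block in self.cnn:
                x = block(x)
            parts.append(self.h1_proj(x) + self.h1_pos)
        if c13 is not None:
            bits = Tensor(np.asarray(c13, dtype=np.float32)[:, :, None])
            parts.append(bits * self.c13_val + self.c13_pos)
        if len(parts) == 1:
            return parts[0]
        from .autograd import concat

        return concat(parts, axis=1)

    def encode(self, h1: np.ndarray | None, c13: np.ndarray | None) -> tuple[Tensor, None]:
        memory = self._run_encoder(self.features(h1, c13), mask=None)
        return memory, None

    def substructure_probabilities(self, memory: Tensor) -> tuple[Tensor, Tensor]:
        """(probabilities, logits) of shape (B, V), probabilities in (0, 1)."""
        x = memory
        for layer in self.substruct_layers:
            x = layer(x, None, self._drop_rng)
        pooled = self.substruct_norm(x).mean(axis=1)
        logits = self.substruct_proj(pooled)
        return logits.sigmoid(), logits

    def forward(
        self,
        h1: np.ndarray | None,
        c13: np.ndarray | None,
        tgt_in: np.ndarray,
    ) -> tuple[Tensor, Tensor, Tensor]:
        """Returns (SMILES logits, substructure probabilities, substructure logits)."""
        memory, _ = self.encode(h1, c13)
        smiles_logits = self.decode(memory, None, tgt_in)
        probs, sub_logits = self.substructure_probabilities(memory)
        return smiles_logits, probs, sub_logits

    __call__ = forward


def build_multitask(config: MultitaskConfig, seed: int = 0) -> Multitask:
    """Construct a multitask model with seeded initialization."""
    return Multitask(config, seed=seed)


class TransferError(ValueError):
    """Raised when pretrained weights cannot be mapped onto the target model."""


# parameter-name prefixes copied from the pretrained substructure-to-structure
# model into the multitask model
TRANSFER_PREFIXES = (
    "token_embedding.",
    "encoder_layers.",
    "encoder_norm.",
    "decoder_layers.",
    "decoder_norm.",
    "out_proj.",
)


def transfer_weights(pretrained, target: Multitask) -> list[str]:
    """Initialize the target's transformer core from a pretrained checkpoint.

    ``pretrained`` is a :class:`~nmr2struct.nets.checkpoint.Checkpoint` from
    the substructure-to-structure task (or a Substruct2Struct model).  All
    encoder layers, decoder layers, the token embedding and the output
    projection are copied; spectral frontends and the substructure head keep
    their fresh initialization.  Returns the list of transferred parameter
    names.
    """
    from .checkpoint import Checkpoint

    if isinstance(pretrained, Checkpoint):
        state = pretrained.state
        src_alpha = pretrained.alphabet_tokens
    else:
        state = pretrained.state_dict()
        src_alpha = None
    tgt_params = target.named_parameters()
    transferred = []
    for name, param in tgt_params.items():
        if not name.startswith(TRANSFER_PREFIXES):
            continue
        if name not in state:
            raise TransferError(f"pretrained checkpoint lacks tensor {name!r}")
        src = state[name]
        if src.shape != param.data.shape:
            raise TransferError(
                f"shape mismatch for {name!r}: {src.shape} vs {param.data.shape}"
            )
        param.data = src.astype(np.float32).copy()
        transferred.append(name)
    if not transferred:
        raise TransferError("no tensors transferred")
    return transferred
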