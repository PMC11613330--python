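"""Single-file checkpoints: config + named weights + alphabet + vocabulary hash.

Stored as an ``.npz`` archive whose ``__meta__`` entry carries a JSON header
(model kind, config, alphabet tokens, vocabulary hash, training manifest)
and whose remaining entries are the named weight arrays.  Loaders verify
alphabet and vocabulary hashes before weights are accepted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .transformer import Substruct2Struct, TransformerConfig
from .multitask import Multitask, MultitaskConfig

__all__ = ["Checkpoint", "save_checkpoint", "load_checkpoint", "build_from_checkpoint"]


@dataclass
class Checkpoint:
    kind: str                      # "substruct2struct" | "multitask"
    config: dict
    state: dict[str, np.ndarray]
    alphabet_tokens: tuple[str, ...]
    vocab_hash: str
    manifest: dict

    def transformer_config(self) -> TransformerConfig:
        cfg = self.config["transformer"] if self.kind == "multitask" else self.config
        return TransformerConfig(**cfg)


def _config_dict(model) -> tuple[str, dict]:
    if isinstance(model, Multitask):
        d = asdict(model.mcfg)
        d["transformer"] = asdict(model.mcfg.transformer)
        return "multitask", d
    if isinstance(model, Substruct2Struct):
        return "substruct2struct", asdict(model.cfg)
    raise TypeError(f"cannot checkpoint {type(model).__name__}")


def save_checkpoint(
    path: str | Path,
    model,
    alphabet_tokens,
    vocab_hash: str,
    manifest: dict | None = None,
) -> None:
    kind, cfg = _config_dict(model)
    meta = {
        "kind": kind,
        "config": cfg,
        "alphabet": list(alphabet_tokens),
        "vocab_hash": vocab_hash,
        "manifest": manifest or {},
    }
    arrays = {f"w::{k}": v for k, v in model.state_dict().items()}
    with open(path, "wb") as fh:
        np.savez(fh, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> Checkpoint:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        state = {
            k[len("w::"):]: archive[k].copy() for k in archive.files if k.startswith("w::")
        }
    return Checkpoint(
        kind=meta["kind"],
        config=meta["config"],
        state=state,
        alphabet_tokens=tuple(meta["alphabet"]),
        vocab_hash=meta["vocab_hash"],
        manifest=meta["manifest"],
    )


def build_from_checkpoint(
    ckpt: Checkpoint,
    expected_alphabet=None,
    expected_vocab_hash: str | None = None,
):
    """Reconstruct the model from a checkpoint, verifying content hashes."""
    if expected_alphabet is not None and tuple(expected_alphabet) != ckpt.alphabet_tokens:
        raise ValueError("checkpoint alphabet does not match the expected alphabet")
    if expected_vocab_hash is not None and expected_vocab_hash != ckpt.vocab_hash:
        raise ValueError("checkpoint vocabulary hash does not match")
    if ckpt.kind == "substruct2struct":
        model = Substruct2Struct(TransformerConfig(**ckpt.config))
    elif ckpt.kind == "multitask":
        cfg = dict(ckpt.config)
        cfg["transformer"] = TransformerConfig(**cfg["transformer"])
        for key in ("cnn_channels", "cnn_kernels", "cnn_strides"):
            cfg[key] = tuple(cfg[key])
        model = Multitask(MultitaskConfig(**cfg))
    else:
        raise ValueError(f"unknown checkpoint kind {ckpt.kind!r}")
    model.load_state_dict(ckpt.state)
    return model.eval()
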