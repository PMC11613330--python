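"""Dataset splitting, batching with right padding and masks, losses, training.

Targets are SMILES token sequences framed as START + tokens + STOP; batches
are right-padded with index 0 and carry boolean masks marking the real
(non-padded) positions.  The multitask objective is
``loss_structure + lam * loss_substructure``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .chem import TokenAlphabet
from .nets.autograd import Tensor, cross_entropy_masked
from .nets.multitask import Multitask
from .nets.transformer import Substruct2Struct
from .simulate import Dataset

__all__ = [
    "SplitSpec",
    "Batch",
    "TrainSchedule",
    "DivergenceError",
    "split_dataset",
    "collate",
    "loss_structure",
    "loss_substructure",
    "Adam",
    "fit",
    "FitResult",
]


@dataclass(frozen=True)
class SplitSpec:
    """Random train/validation/test split fractions (default 80/10/10)."""

    train: float = 0.8
    val: float = 0.1
    test: float = 0.1
    seed: int = 0

    def __post_init__(self):
        fracs = (self.train, self.val, self.test)
        if any(f < 0 for f in fracs) or abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("split fractions must be non-negative and sum to 1")


def split_dataset(n: int, spec: SplitSpec = SplitSpec()) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive index lists of sizes ⌊train·n⌋ / ⌊val·n⌋ / remainder."""
    if n < 10:
        raise ValueError("need at least 10 records to split")
    perm = np.random.default_rng(spec.seed).permutation(n)
    n_train = int(np.floor(spec.train * n))
    n_val = int(np.floor(spec.val * n))
    return perm[:n_train], perm[n_train : n_train + n_val], perm[n_train + n_val :]


@dataclass
class Batch:
    """Right-padded model inputs for one step.

    ``src`` holds presence-index sequences (substructure-to-structure task);
    ``h1``/``c13`` hold spectral tensors (multitask).  ``tgt_in`` is
    START + tokens (decoder input), ``tgt_out`` tokens + STOP (labels);
    ``tgt_mask`` marks non-padded label positions.
    """

    src: np.ndarray | None
    h1: np.ndarray | None
    c13: np.ndarray | None
    tgt_in: np.ndarray
    tgt_out: np.ndarray
    tgt_mask: np.ndarray
    fingerprints: np.ndarray
    smiles: list[str]

    def __len__(self) -> int:
        return len(self.smiles)


def collate(
    dataset: Dataset,
    indices: Sequence[int],
    max_src_len: int | None = None,
    max_tgt_len: int | None = None,
) -> Batch:
    """Assemble a right-padded batch from dataset rows.

    Raises if a record exceeds the configured maximum lengths, naming it.
    """
    idx = list(indices)
    if not idx:
        raise ValueError("empty batch")
    alphabet = dataset.alphabet
    pres = [dataset.presence_indices[i] for i in idx]
    toks = [dataset.token_ids[i] for i in idx]
    for i, (p, t) in zip(idx, zip(pres, toks)):
        if max_src_len is not None and len(p) > max_src_len:
            raise ValueError(f"record {dataset.smiles[i]!r}: source length {len(p)} > {max_src_len}")
        if max_tgt_len is not None and len(t) > max_tgt_len:
            raise ValueError(f"record {dataset.smiles[i]!r}: target length {len(t)} > {max_tgt_len}")
    S = max(len(p) for p in pres)
    T = max(len(t) for t in toks) + 1  # room for START in, STOP out
    B = len(idx)
    src = np.zeros((B, S), dtype=np.int64)
    tgt_in = np.zeros((B, T), dtype=np.int64)
    tgt_out = np.zeros((B, T), dtype=np.int64)
    mask = np.zeros((B, T), dtype=bool)
    for r, (p, t) in enumerate(zip(pres, toks)):
        src[r, : len(p)] = p
        tgt_in[r, 0] = alphabet.start_index
        tgt_in[r, 1 : len(t) + 1] = t
        tgt_out[r, : len(t)] = t
        tgt_out[r, len(t)] = alphabet.stop_index
        mask[r, : len(t) + 1] = True
    return Batch(
        src=src,
        h1=dataset.processed_1h[idx],
        c13=dataset.binned_13c[idx].astype(np.float32),
        tgt_in=tgt_in,
        tgt_out=tgt_out,
        tgt_mask=mask,
        fingerprints=dataset.fingerprints[idx].astype(np.float32),
        smiles=[dataset.smiles[i] for i in idx],
    )


def loss_structure(logits: Tensor, targets: np.ndarray, mask: np.ndarray) -> Tensor:
    """Mean token-level cross-entropy over non-padded target positions."""
    if not isinstance(logits, Tensor):
        logits = Tensor(logits)
    return cross_entropy_masked(logits, targets, mask)


def loss_substructure(probabilities, truth) -> Tensor:
    """Mean binary cross-entropy of substructure presence probabilities."""
    if not isinstance(probabilities, Tensor):
        probabilities = Tensor(np.asarray(probabilities, dtype=np.float32))
    truth_arr = np.asarray(truth, dtype=np.float32)
    p = probabilities.clip(1e-7, 1.0 - 1e-7)
    ll = Tensor(truth_arr) * p.log() + Tensor(1.0 - truth_arr) * (1.0 - p).log()
    return -ll.mean()


class Adam:
    """Adam optimizer with global-norm gradient clipping."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8,
                 clip_norm: float | None = 1.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((p.grad**2).sum()) for p in self.params if p.grad is not None))
            scale = self.clip_norm / (total + 1e-12) if total > self.clip_norm else 1.0
        else:
            scale = 1.0
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad * scale
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class DivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass
class TrainSchedule:
    epochs: int = 20
    batch_size: int = 64
    lr: float = 1e-3
    patience: int | None = None    # early stopping on validation loss
    seed: int = 0
    clip_norm: float = 1.0
    max_tgt_len: int = 62


@dataclass
class FitResult:
    history: list[dict]
    best_state: dict
    best_val_loss: float
    best_epoch: int


def _batch_losses(model, batch: Batch) -> tuple[Tensor, float, float]:
    """(total loss tensor, structure loss value, substructure loss value)."""
    if isinstance(model, Multitask):
        mode = model.mcfg.modality
        h1 = batch.h1 if mode in ("h1", "both") else None
        c13 = batch.c13 if mode in ("c13", "both") else None
        logits, probs, _ = model(h1, c13, batch.tgt_in)
        ls = loss_structure(logits, batch.tgt_out, batch.tgt_mask)
        lam = model.mcfg.lam
        if lam > 0:
            lb = loss_substructure(probs, batch.fingerprints)
            return ls + lam * lb, ls.item(), lb.item()
        return ls, ls.item(), 0.0
    logits = model(batch.src, batch.tgt_in)
    ls = loss_structure(logits, batch.tgt_out, batch.tgt_mask)
    return ls, ls.item(), 0.0


def evaluate_loss(model, dataset: Dataset, indices, batch_size: int = 128,
                  max_tgt_len: int | None = None) -> float:
    """Teacher-forced total loss over an index set (no parameter updates)."""
    model.eval()
    total, n = 0.0, 0
    idx = np.asarray(indices)
    for lo in range(0, len(idx), batch_size):
        batch = collate(dataset, idx[lo : lo + batch_size], max_tgt_len=max_tgt_len)
        loss, _, _ = _batch_losses(model, batch)
        total += loss.item() * len(batch)
        n += len(batch)
    return total / max(n, 1)


def fit(
    model,
    dataset: Dataset,
    train_indices,
    val_indices,
    schedule: TrainSchedule = TrainSchedule(),
) -> FitResult:
    """Train a model, keeping the parameter state at the best validation loss.

    Fully seeded: batch order and dropout derive from ``schedule.seed``.
    Raises :class:`DivergenceError` if the loss becomes non-finite.
    """
    rng = np.random.default_rng(schedule.seed)
    model.reseed_dropout(schedule.seed + 1)
    opt = Adam(model.parameters(), lr=schedule.lr, clip_norm=schedule.clip_norm)
    train_idx = np.asarray(train_indices)
    history: list[dict] = []
    best_val, best_state, best_epoch = np.inf, model.state_dict(), -1
    bad_epochs = 0
    for epoch in range(schedule.epochs):
        model.train()
        order = rng.permutation(len(train_idx))
        ep_loss, n_seen = 0.0, 0
        for lo in range(0, len(order), schedule.batch_size):
            batch = collate(dataset, train_idx[order[lo : lo + schedule.batch_size]],
                            max_tgt_len=schedule.max_tgt_len)
            loss, ls, lb = _batch_losses(model, batch)
            if not np.isfinite(loss.item()):
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch}: structure={ls}, substructure={lb}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_loss += loss.item() * len(batch)
            n_seen += len(batch)
        train_loss = ep_loss / n_seen
        val_loss = (
            evaluate_loss(model, dataset, val_indices, max_tgt_len=schedule.max_tgt_len)
            if len(np.asarray(val_indices)) else train_loss
        )
        history.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        if val_loss < best_val:
            best_val, best_state, best_epoch = val_loss, model.state_dict(), epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if schedule.patience is not None and bad_epochs > schedule.patience:
                break
    model.load_state_dict(best_state)
    model.eval()
    return FitResult(history=history, best_state=best_state,
                     best_val_loss=best_val, best_epoch=best_epoch)
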