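"""Inference by top-k sampling and the evaluation metric suite.

A prediction set holds the 15 SMILES strings sampled for one input
(possibly invalid, possibly duplicated — kept as drawn).  A prediction is
*correct* when any valid sample canonicalizes to exactly the target's
canonical SMILES.  Failure analysis uses the maximum Tanimoto similarity
of the valid-but-incorrect samples; substructure output is scored by
micro-averaged F1 at a 0.5 decision boundary and by probability
calibration against the <0.1 / >0.9 confidence bands.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np

from .chem import CanonicalSmiles, canonicalize, detokenize, tanimoto, InvalidMoleculeError, TokenizationError
from .nets.autograd import Tensor, no_grad
from .nets.multitask import Multitask
from .nets.transformer import IncrementalDecoder, Substruct2Struct
from .simulate import Dataset

__all__ = [
    "PredictionSet",
    "EvalReport",
    "sample_topk",
    "is_correct",
    "topn_accuracy",
    "best_incorrect_tanimoto",
    "substructure_f1",
    "calibration_report",
    "problem_size_fit",
    "evaluate_model",
]

DEFAULT_K = 5
DEFAULT_N_SAMPLES = 15


@dataclass
class PredictionSet:
    """The sampled SMILES strings for one input, with validity annotations."""

    input_id: int
    samples: list[str]
    valid: list[bool] = field(default_factory=list)
    canonical: list[str | None] = field(default_factory=list)

    def __post_init__(self):
        if not self.valid:
            for s in self.samples:
                try:
                    self.canonical.append(canonicalize(s).text)
                    self.valid.append(True)
                except (InvalidMoleculeError, TokenizationError):
                    self.canonical.append(None)
                    self.valid.append(False)


def _sample_step(logits: np.ndarray, k: int, rng: np.random.Generator,
                 forbidden: Sequence[int]) -> np.ndarray:
    """Draw one token per row from the renormalized top-k distribution."""
    logits = logits.copy()
    logits[:, list(forbidden)] = -np.inf
    k = min(k, logits.shape[1])
    top = np.argpartition(-logits, k - 1, axis=1)[:, :k]          # (M, k)
    top_logits = np.take_along_axis(logits, top, axis=1)
    z = top_logits - top_logits.max(axis=1, keepdims=True)
    p = np.exp(z)
    p /= p.sum(axis=1, keepdims=True)
    if k == 1:
        choice = np.zeros(len(logits), dtype=np.int64)
    else:
        u = rng.random((len(logits), 1))
        choice = (p.cumsum(axis=1) < u).sum(axis=1)
        choice = np.minimum(choice, k - 1)
    return np.take_along_axis(top, choice[:, None], axis=1)[:, 0]


def sample_topk(
    model,
    *,
    src: np.ndarray | None = None,
    h1: np.ndarray | None = None,
    c13: np.ndarray | None = None,
    alphabet,
    k: int = DEFAULT_K,
    n_samples: int = DEFAULT_N_SAMPLES,
    max_len: int = 60,
    seed: int = 0,
    batch_size: int = 512,
) -> list[PredictionSet]:
    """Generate ``n_samples`` SMILES per input by top-k autoregressive sampling.

    Each sample restricts the next-token distribution to the ``k`` most
    probable tokens, renormalizes, and draws one; generation terminates on
    the stop token or at ``max_len``.  PAD is never sampled.  Fully seeded.
    """
    model.eval()
    with no_grad():
        if isinstance(model, Multitask):
            n_inputs = len(h1) if h1 is not None else len(c13)
            memory, src_pad = model.encode(h1, c13)
        else:
            n_inputs = len(src)
            memory, src_pad = model.encode(src)
    rng = np.random.default_rng(seed)
    mem = np.repeat(memory.data, n_samples, axis=0)
    pad = np.repeat(src_pad, n_samples, axis=0) if src_pad is not None else None
    M = n_inputs * n_samples
    start, stop, pad_idx = alphabet.start_index, alphabet.stop_index, alphabet.pad_index
    all_tokens = np.full((M, max_len), pad_idx, dtype=np.int64)

    for lo in range(0, M, batch_size):
        hi = min(lo + batch_size, M)
        prev = np.full(hi - lo, start, dtype=np.int64)
        alive = np.ones(hi - lo, dtype=bool)
        pad_b = pad[lo:hi] if pad is not None else None
        decoder = IncrementalDecoder(model, mem[lo:hi], pad_b)
        for t in range(max_len):
            logits = decoder.step(prev)
            nxt = _sample_step(logits, k, rng, forbidden=[pad_idx])
            nxt = np.where(alive, nxt, pad_idx)
            all_tokens[lo:hi, t] = nxt
            alive &= nxt != stop
            if not alive.any():
                break
            prev = np.where(alive, nxt, pad_idx)

    out: list[PredictionSet] = []
    for i in range(n_inputs):
        samples = []
        for j in range(n_samples):
            row = all_tokens[i * n_samples + j]
            toks = []
            for idx in row:
                if idx in (stop, pad_idx):
                    break
                toks.append(alphabet.tokens[idx])
            samples.append(detokenize(toks))
        out.append(PredictionSet(input_id=i, samples=samples))
    return out


def is_correct(pred: PredictionSet, target: CanonicalSmiles | str) -> bool:
    """True iff any valid sample canonicalizes to the target's canonical text."""
    tgt = target.text if isinstance(target, CanonicalSmiles) else canonicalize(target).text
    return any(c == tgt for c in pred.canonical if c is not None)


def topn_accuracy(
    predictions: Sequence[PredictionSet],
    targets: Sequence[CanonicalSmiles | str],
    heavy_atoms: Sequence[int] | None = None,
) -> tuple[float, dict[int, float]]:
    """Overall fraction correct and, when sizes are given, the rate per size."""
    if len(predictions) != len(targets):
        raise ValueError("predictions and targets differ in length")
    flags = np.array([is_correct(p, t) for p, t in zip(predictions, targets)])
    by_size: dict[int, float] = {}
    if heavy_atoms is not None:
        sizes = np.asarray(heavy_atoms)
        if len(sizes) != len(flags):
            raise ValueError("heavy_atoms length mismatch")
        for s in np.unique(sizes):
            by_size[int(s)] = float(flags[sizes == s].mean())
    return float(flags.mean()), by_size


def best_incorrect_tanimoto(
    predictions: Sequence[PredictionSet],
    targets: Sequence[CanonicalSmiles | str],
) -> tuple[list[float], dict[str, float]]:
    """Max Tanimoto of valid samples for each incorrectly-predicted target.

    Correctly-predicted targets and invalid strings are excluded; targets
    with no valid incorrect sample are omitted.  Returns the raw list and
    a summary with the fraction ≥ 0.50 and the mean.
    """
    if len(predictions) != len(targets):
        raise ValueError("predictions and targets differ in length")
    sims: list[float] = []
    n_omitted = 0
    for pred, target in zip(predictions, targets):
        if is_correct(pred, target):
            continue
        cands = {c for c in pred.canonical if c is not None}
        if not cands:
            n_omitted += 1
            continue
        sims.append(max(tanimoto(c, target) for c in cands))
    summary = {
        "n": len(sims),
        "n_omitted": n_omitted,
        "fraction_ge_0.5": float(np.mean([s >= 0.5 for s in sims])) if sims else float("nan"),
        "mean": float(np.mean(sims)) if sims else float("nan"),
    }
    return sims, summary


def substructure_f1(
    probabilities: np.ndarray, truth: np.ndarray, threshold: float = 0.5
) -> dict[str, float]:
    """Micro-averaged F1 over all (molecule, substructure) pairs.

    Predictions are binarized at ``threshold``.  With no true and no
    predicted positives, F1 is 1.0 by convention.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(truth).astype(bool)
    if p.shape != y.shape:
        raise ValueError("probabilities and truth shapes differ")
    pred = p >= threshold
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    fn = int(np.sum(~pred & y))
    tn = int(np.sum(~pred & ~y))
    if tp + fp + fn == 0:
        f1, precision, recall = 1.0, 1.0, 1.0
    else:
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * tp / (2 * tp + fp + fn)
    return {"f1": f1, "precision": precision, "recall": recall,
            "tp": tp, "fp": fp, "tn": tn, "fn": fn}


def calibration_report(
    probabilities: np.ndarray, truth: np.ndarray, lo: float = 0.1, hi: float = 0.9
) -> dict[str, float | None]:
    """Accuracy inside the confident bands and the mass between them.

    ``accuracy_low``: fraction of entries with p < lo whose truth is 0;
    ``accuracy_high``: fraction with p > hi whose truth is 1;
    ``fraction_mid``: fraction with lo ≤ p ≤ hi (boundary values count as
    mid — the bands are strict inequalities).  Empty bands report None.
    """
    p = np.asarray(probabilities, dtype=float).ravel()
    y = np.asarray(truth).astype(bool).ravel()
    if p.shape != y.shape:
        raise ValueError("probabilities and truth shapes differ")
    low, high = p < lo, p > hi
    acc_low = float((~y[low]).mean()) if low.any() else None
    acc_high = float(y[high].mean()) if high.any() else None
    fraction_mid = float((~low & ~high).mean()) if p.size else None
    return {"accuracy_low": acc_low, "accuracy_high": acc_high, "fraction_mid": fraction_mid}


def problem_size_fit(counts: dict[int, float]) -> Callable[[Sequence[int]], np.ndarray]:
    """Exponential extrapolation of molecule counts versus heavy-atom number.

    Least-squares fit of log10(count) against heavy atoms; the returned
    function maps sizes to predicted counts.
    """
    if len(counts) < 2:
        raise ValueError("need at least two (size, count) points")
    sizes = np.array(sorted(counts), dtype=float)
    values = np.array([counts[int(s)] for s in sizes], dtype=float)
    if np.any(values <= 0):
        raise ValueError("counts must be positive")
    slope, intercept = np.polyfit(sizes, np.log10(values), 1)

    def predict(query):
        q = np.asarray(query, dtype=float)
        return 10.0 ** (slope * q + intercept)

    return predict


@dataclass
class EvalReport:
    """Full metric suite for one model on one split."""

    n_molecules: int
    top_n_accuracy: float
    accuracy_by_heavy_atoms: dict[int, float]
    tanimoto_summary: dict[str, float]
    tanimoto_values: list[float]
    f1: dict[str, float] | None
    calibration: dict[str, float | None] | None
    sampling: dict

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(asdict(self), indent=indent, default=float)


def evaluate_model(
    model,
    dataset: Dataset,
    indices: Sequence[int],
    k: int = DEFAULT_K,
    n_samples: int = DEFAULT_N_SAMPLES,
    max_len: int = 60,
    seed: int = 0,
) -> EvalReport:
    """Sample predictions for a split and compute the full metric suite."""
    idx = np.asarray(indices)
    targets = [CanonicalSmiles(dataset.smiles[i]) for i in idx]
    heavy = dataset.heavy_atoms[idx]
    if isinstance(model, Multitask):
        mode = model.mcfg.modality
        h1 = dataset.processed_1h[idx] if mode in ("h1", "both") else None
        c13 = dataset.binned_13c[idx].astype(np.float32) if mode in ("c13", "both") else None
        preds = sample_topk(model, h1=h1, c13=c13, alphabet=dataset.alphabet,
                            k=k, n_samples=n_samples, max_len=max_len, seed=seed)
        with no_grad():
            memory, _ = model.encode(h1, c13)
            probs = model.substructure_probabilities(memory)[0].data
        f1 = substructure_f1(probs, dataset.fingerprints[idx])
        calib = calibration_report(probs, dataset.fingerprints[idx])
    else:
        src_list = [dataset.presence_indices[i] for i in idx]
        S = max(len(s) for s in src_list)
        src = np.zeros((len(idx), S), dtype=np.int64)
        for r, s in enumerate(src_list):
            src[r, : len(s)] = s
        preds = sample_topk(model, src=src, alphabet=dataset.alphabet,
                            k=k, n_samples=n_samples, max_len=max_len, seed=seed)
        f1, calib = None, None
    acc, by_size = topn_accuracy(preds, targets, heavy)
    sims, summary = best_incorrect_tanimoto(preds, targets)
    return EvalReport(
        n_molecules=len(idx),
        top_n_accuracy=acc,
        accuracy_by_heavy_atoms=by_size,
        tanimoto_summary=summary,
        tanimoto_values=sims,
        f1=f1,
        calibration=calib,
        sampling={"k": k, "n_samples": n_samples, "max_len": max_len, "seed": seed},
    )
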