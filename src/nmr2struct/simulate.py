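"""Synthetic fixtures: small-molecule enumeration and a toy 1D NMR simulator.

The simulator exists to give the spectrum↔structure mapping a learnable,
information-bearing signal at desk scale — it is deliberately crude
(additive shift increments, first-order multiplets, Lorentzian lines) and
makes no claim of chemical-shift accuracy.  Enumeration covers acyclic and
monocyclic C/N/O molecules up to 8 heavy atoms with standard valences.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem

from .chem import (
    CanonicalSmiles,
    SubstructureVocabulary,
    TokenAlphabet,
    build_alphabet,
    canonicalize,
    compute_fingerprint,
    to_presence_indices,
    tokenize,
)
from .spectra import (
    BinConfig,
    GridConfig,
    DEFAULT_BINS,
    DEFAULT_GRID,
    PeakList13C,
    RawSpectrum1H,
    bin_13c,
    preprocess_1h,
)

__all__ = [
    "ShiftModel",
    "enumerate_molecules",
    "simulate_13c",
    "simulate_1h",
    "Dataset",
    "make_dataset",
    "load_dataset",
]

_MAX_VALENCE = {"C": 4, "N": 3, "O": 2}


def _canonical_or_none(mol: Chem.Mol) -> str | None:
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return Chem.MolToSmiles(mol, canonical=True, isomericSmiles=False)


def _grow_by_atom(smiles: str, elements: Sequence[str]) -> set[str]:
    """All molecules obtained by bonding one new atom to an existing one."""
    out: set[str] = set()
    base = Chem.MolFromSmiles(smiles)
    for ai in range(base.GetNumAtoms()):
        free = base.GetAtomWithIdx(ai).GetTotalNumHs()
        if free == 0:
            continue
        for elem in elements:
            for order in range(1, min(free, _MAX_VALENCE[elem], 3) + 1):
                rw = Chem.RWMol(base)
                new_idx = rw.AddAtom(Chem.Atom(elem))
                rw.AddBond(ai, new_idx, Chem.BondType.values[order])
                smi = _canonical_or_none(rw.GetMol())
                if smi is not None:
                    out.add(smi)
    return out


def _close_rings(smiles: str) -> set[str]:
    """All monocyclic molecules obtained by one new bond in an acyclic graph."""
    out: set[str] = set()
    base = Chem.MolFromSmiles(smiles)
    if base.GetRingInfo().NumRings() > 0:
        return out
    n = base.GetNumAtoms()
    for i in range(n):
        fi = base.GetAtomWithIdx(i).GetTotalNumHs()
        if fi == 0:
            continue
        for j in range(i + 1, n):
            if base.GetBondBetweenAtoms(i, j) is not None:
                continue
            fj = base.GetAtomWithIdx(j).GetTotalNumHs()
            for order in range(1, min(fi, fj, 3) + 1):
                rw = Chem.RWMol(base)
                rw.AddBond(i, j, Chem.BondType.values[order])
                smi = _canonical_or_none(rw.GetMol())
                if smi is None:
                    continue
                reparsed = Chem.MolFromSmiles(smi)
                if reparsed is None:
                    continue
                # GetSSSR initializes ring info (MolFromSmiles occasionally
                # leaves it uninitialized) and returns the SSSR ring set
                if len(Chem.GetSSSR(reparsed)) == 1:
                    out.add(smi)
    return out


def enumerate_molecules(
    max_heavy: int, elements: Iterable[str] = ("C", "N", "O")
) -> list[CanonicalSmiles]:
    """Enumerate all acyclic and monocyclic molecules up to ``max_heavy`` atoms.

    Standard valences (C:4, N:3, O:2), neutral closed-shell molecules only.
    Output is deduplicated by canonical SMILES and deterministically ordered
    by (heavy-atom count, canonical string).
    """
    elements = sorted(set(elements))
    if unknown := set(elements) - set(_MAX_VALENCE):
        raise ValueError(f"unsupported elements: {sorted(unknown)}")
    if not 1 <= max_heavy <= 8:
        raise ValueError("max_heavy must be between 1 and 8")

    level: set[str] = {
        Chem.MolToSmiles(Chem.MolFromSmiles(e)) for e in elements
    }
    seen: set[str] = set(level)
    for _ in range(2, max_heavy + 1):
        grown: set[str] = set()
        for smi in level:
            grown |= _grow_by_atom(smi, elements)
        cyclic: set[str] = set()
        for smi in grown:
            cyclic |= _close_rings(smi)
        level = grown | cyclic
        seen |= level

    def sort_key(smi: str):
        return (Chem.MolFromSmiles(smi).GetNumHeavyAtoms(), smi)

    return [CanonicalSmiles(s) for s in sorted(seen, key=sort_key)]


@dataclass(frozen=True)
class ShiftModel:
    """Parameters of the toy NMR forward model.

    Chemical shifts are additive: a base shift per atom-environment class
    plus neighbor increments, plus a small deterministic per-environment
    offset (hashed from the radius-2 atom environment) that separates
    otherwise-identical environment classes across molecules.
    """

    j_hz: float = 7.0                # vicinal coupling constant
    freq_mhz: float = 400.0          # spectrometer frequency (Hz→ppm conversion)
    linewidth_ppm: float = 0.004     # Lorentzian half-width at half-maximum
    noise_sigma: float = 0.0         # Gaussian noise, relative to peak maximum
    seed: int = 0
    n_points: int = 32768            # raw acquisition length
    span_ppm: tuple[float, float] = (-2.0, 12.0)
    env_jitter_1h: float = 0.3       # half-range of the per-environment offset (ppm)
    env_jitter_13c: float = 6.0

    @property
    def j_ppm(self) -> float:
        return self.j_hz / self.freq_mhz


def _env_hash_unit(mol: Chem.Mol, atom_idx: int, radius: int = 2) -> float:
    """Deterministic value in [-1, 1] from the atom's radius-2 environment."""
    try:
        bonds = Chem.FindAtomEnvironmentOfRadiusN(mol, radius, atom_idx)
        sub = Chem.PathToSubmol(mol, bonds) if bonds else None
        key = Chem.MolToSmiles(sub) if sub is not None and sub.GetNumAtoms() else ""
    except Exception:
        key = ""
    sym = mol.GetAtomWithIdx(atom_idx).GetSymbol()
    h = hashlib.sha256(f"{sym}|{key}".encode()).digest()
    return int.from_bytes(h[:4], "big") / 2**31 - 1.0


def _equivalence_classes(mol: Chem.Mol) -> dict[int, list[int]]:
    """Group atom indices by canonical rank (symmetry-equivalent atoms share a rank)."""
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=False))
    classes: dict[int, list[int]] = {}
    for idx, rank in enumerate(ranks):
        classes.setdefault(rank, []).append(idx)
    return classes


def _carbon_shift(mol: Chem.Mol, idx: int, model: ShiftModel) -> float:
    atom = mol.GetAtomWithIdx(idx)
    nbrs = list(atom.GetNeighbors())
    has_double_o = any(
        n.GetSymbol() == "O"
        and mol.GetBondBetweenAtoms(idx, n.GetIdx()).GetBondTypeAsDouble() == 2.0
        for n in nbrs
    )
    triple_n = any(
        n.GetSymbol() == "N"
        and mol.GetBondBetweenAtoms(idx, n.GetIdx()).GetBondTypeAsDouble() == 3.0
        for n in nbrs
    )
    if atom.GetIsAromatic():
        base = 128.0
    elif has_double_o:
        base = 172.0 if any(n.GetSymbol() in "ON" and not
                            mol.GetBondBetweenAtoms(idx, n.GetIdx()).GetBondTypeAsDouble() == 2.0
                            for n in nbrs) else 198.0
    elif triple_n:
        base = 118.0
    elif atom.GetHybridization() == Chem.HybridizationType.SP:
        base = 75.0
    elif atom.GetHybridization() == Chem.HybridizationType.SP2:
        base = 130.0
    else:
        base = 10.0
        for n in nbrs:
            base += {"C": 9.0, "N": 20.0, "O": 40.0}.get(n.GetSymbol(), 0.0)
    return base + model.env_jitter_13c * _env_hash_unit(mol, idx)


def simulate_13c(mol: CanonicalSmiles, model: ShiftModel | None = None) -> PeakList13C:
    """One peak per symmetry-distinct carbon environment (decoupled spectrum)."""
    model = model or ShiftModel()
    m = mol.mol()
    lo, hi = DEFAULT_BINS.lo, DEFAULT_BINS.hi
    shifts = []
    for rank, idxs in sorted(_equivalence_classes(m).items()):
        if m.GetAtomWithIdx(idxs[0]).GetSymbol() != "C":
            continue
        shifts.append(float(np.clip(_carbon_shift(m, idxs[0], model), lo, hi)))
    return PeakList13C(np.array(sorted(shifts)))


def _proton_shift(mol: Chem.Mol, idx: int, model: ShiftModel) -> float:
    atom = mol.GetAtomWithIdx(idx)
    sym = atom.GetSymbol()
    nbrs = list(atom.GetNeighbors())
    if sym == "O":
        base = 3.6
    elif sym == "N":
        base = 1.9
    elif atom.GetIsAromatic():
        base = 7.2
    else:
        has_double_o = any(
            n.GetSymbol() == "O"
            and mol.GetBondBetweenAtoms(idx, n.GetIdx()).GetBondTypeAsDouble() == 2.0
            for n in nbrs
        )
        if has_double_o:
            base = 9.6  # aldehyde/formyl
        elif atom.GetHybridization() == Chem.HybridizationType.SP2:
            base = 5.6
        elif atom.GetHybridization() == Chem.HybridizationType.SP:
            base = 2.4
        else:
            base = 0.9
            for n in nbrs:
                base += {"C": 0.35, "N": 1.4, "O": 2.4}.get(n.GetSymbol(), 0.0)
            base += 0.25 * max(0, len(nbrs) - 1)
    return base + model.env_jitter_1h * _env_hash_unit(mol, idx)


def simulate_1h(mol: CanonicalSmiles, model: ShiftModel | None = None) -> RawSpectrum1H:
    """First-order stick-and-lineshape ^1H spectrum on the raw acquisition grid.

    Each symmetry-distinct H-bearing environment contributes an (n+1)-line
    multiplet (n = hydrogens on adjacent heavy atoms, carbon-bound protons
    only) with binomial intensities and Lorentzian lineshape; the multiplet
    integral is proportional to the environment's hydrogen count.  Heteroatom
    protons appear as singlets (exchange-decoupled).  Optional Gaussian noise
    is drawn from a generator seeded by (model.seed, molecule).
    """
    model = model or ShiftModel()
    m = mol.mol()
    lo, hi = model.span_ppm
    grid = np.linspace(lo, hi, model.n_points)
    intensity = np.zeros(model.n_points)
    gamma = model.linewidth_ppm
    total_h = 0
    for rank, idxs in sorted(_equivalence_classes(m).items()):
        atom = m.GetAtomWithIdx(idxs[0])
        n_h_per_atom = atom.GetTotalNumHs()
        if n_h_per_atom == 0:
            continue
        n_h = n_h_per_atom * len(idxs)
        total_h += n_h
        center = float(np.clip(_proton_shift(m, idxs[0], model), lo + 0.1, hi - 0.1))
        if atom.GetSymbol() == "C":
            n_coupled = sum(
                nb.GetTotalNumHs() for nb in atom.GetNeighbors() if nb.GetSymbol() == "C"
            )
        else:
            n_coupled = 0
        weights = np.array([_binom(n_coupled, i) for i in range(n_coupled + 1)], dtype=float)
        weights *= n_h / weights.sum()
        positions = center + model.j_ppm * (np.arange(n_coupled + 1) - n_coupled / 2)
        for pos, w in zip(positions, weights):
            # Lorentzian normalized to unit integral, then scaled by H weight
            intensity += (w / np.pi) * gamma / ((grid - pos) ** 2 + gamma**2)
    if total_h == 0:
        return RawSpectrum1H(grid, intensity)  # flagged: all-zero spectrum
    if model.noise_sigma > 0:
        digest = hashlib.sha256(f"{model.seed}|{mol.text}".encode()).digest()
        rng = np.random.default_rng(int.from_bytes(digest[:4], "big"))
        intensity = np.abs(
            intensity + model.noise_sigma * intensity.max() * rng.standard_normal(intensity.shape)
        )
    return RawSpectrum1H(grid, intensity)


def _binom(n: int, k: int) -> int:
    from math import comb

    return comb(n, k)


def _total_h(mol: CanonicalSmiles) -> int:
    return sum(a.GetTotalNumHs() for a in mol.mol().GetAtoms())


# --- dataset assembly -------------------------------------------------------


@dataclass
class Dataset:
    """Aligned per-molecule records for training and evaluation.

    ``processed_1h`` rows are on the configured grid in [0, 1];
    ``binned_13c`` rows are bin indicators; ``fingerprints`` rows follow the
    vocabulary's bit order; ``token_ids`` holds encoded SMILES token indices
    (no START/STOP — those are added at collation).
    """

    smiles: list[str]
    heavy_atoms: np.ndarray
    fingerprints: np.ndarray
    presence_indices: list[np.ndarray]
    token_ids: list[np.ndarray]
    processed_1h: np.ndarray
    binned_13c: np.ndarray
    vocab: SubstructureVocabulary
    alphabet: TokenAlphabet
    manifest: dict

    def __len__(self) -> int:
        return len(self.smiles)

    def subset(self, indices: Sequence[int]) -> "Dataset":
        idx = np.asarray(indices, dtype=np.int64)
        return Dataset(
            smiles=[self.smiles[i] for i in idx],
            heavy_atoms=self.heavy_atoms[idx],
            fingerprints=self.fingerprints[idx],
            presence_indices=[self.presence_indices[i] for i in idx],
            token_ids=[self.token_ids[i] for i in idx],
            processed_1h=self.processed_1h[idx],
            binned_13c=self.binned_13c[idx],
            vocab=self.vocab,
            alphabet=self.alphabet,
            manifest={**self.manifest, "subset_of": self.manifest.get("n_molecules")},
        )


def make_dataset(
    molecules: Sequence[CanonicalSmiles | str],
    model: ShiftModel | None = None,
    vocab: SubstructureVocabulary | None = None,
    alphabet: TokenAlphabet | None = None,
    grid: GridConfig = DEFAULT_GRID,
    binning: BinConfig = DEFAULT_BINS,
    out_dir: str | Path | None = None,
) -> Dataset:
    """Build (and optionally persist) an aligned dataset of spectra and targets.

    If ``alphabet`` is supplied it must cover every token in the corpus;
    otherwise one is built from the corpus.
    """
    from .chem import toy_vocabulary

    model = model or ShiftModel()
    vocab = vocab or toy_vocabulary()
    mols = [m if isinstance(m, CanonicalSmiles) else canonicalize(m) for m in molecules]
    # hydrogen-free molecules (N2, CO2, ...) have no 1H signal to normalize
    n_input = len(mols)
    mols = [m for m in mols if _total_h(m) > 0]
    if alphabet is None:
        alphabet = build_alphabet(mols)
    smiles, heavy, fps, pres, toks = [], [], [], [], []
    h1 = np.zeros((len(mols), grid.count), dtype=np.float32)
    c13 = np.zeros((len(mols), binning.count), dtype=np.int8)
    for i, mol in enumerate(mols):
        smiles.append(mol.text)
        heavy.append(mol.heavy_atoms)
        fp = compute_fingerprint(mol, vocab)
        fps.append(fp)
        pres.append(to_presence_indices(fp))
        try:
            toks.append(alphabet.encode(tokenize(mol.text)))
        except KeyError as e:
            raise ValueError(f"alphabet does not cover {mol.text!r}: {e}") from None
        h1[i] = preprocess_1h(simulate_1h(mol, model), grid)
        c13[i] = bin_13c(simulate_13c(mol, model), binning)
    manifest = {
        "n_molecules": len(mols),
        "n_dropped_no_hydrogen": n_input - len(mols),
        "vocab_name": vocab.name,
        "vocab_hash": vocab.content_hash(),
        "alphabet_hash": alphabet.content_hash(),
        "shift_model": asdict(model),
        "grid": asdict(grid),
        "binning": asdict(binning),
    }
    ds = Dataset(
        smiles=smiles,
        heavy_atoms=np.array(heavy, dtype=np.int64),
        fingerprints=np.stack(fps),
        presence_indices=pres,
        token_ids=toks,
        processed_1h=h1,
        binned_13c=c13,
        vocab=vocab,
        alphabet=alphabet,
        manifest=manifest,
    )
    if out_dir is not None:
        save_dataset(ds, out_dir)
    return ds


def save_dataset(ds: Dataset, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.json").write_text(json.dumps(ds.manifest, indent=2, sort_keys=True))
    (out / "smiles.txt").write_text("\n".join(ds.smiles) + "\n")
    (out / "alphabet.txt").write_text("\n".join(ds.alphabet.tokens) + "\n")
    from .chem import save_vocabulary

    save_vocabulary(ds.vocab, out / "vocabulary.smarts")
    np.save(out / "fingerprints.npy", ds.fingerprints)
    np.save(out / "processed_1h.npy", ds.processed_1h)
    np.save(out / "binned_13c.npy", ds.binned_13c)
    np.save(out / "heavy_atoms.npy", ds.heavy_atoms)


def load_dataset(in_dir: str | Path) -> Dataset:
    from .chem import load_vocabulary

    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    smiles = (src / "smiles.txt").read_text().split()
    alphabet = TokenAlphabet(tuple((src / "alphabet.txt").read_text().splitlines()))
    vocab = load_vocabulary(src / "vocabulary.smarts", name=manifest.get("vocab_name"))
    if vocab.content_hash() != manifest["vocab_hash"]:
        raise ValueError("vocabulary hash mismatch with manifest")
    fps = np.load(src / "fingerprints.npy")
    return Dataset(
        smiles=smiles,
        heavy_atoms=np.load(src / "heavy_atoms.npy"),
        fingerprints=fps,
        presence_indices=[to_presence_indices(fp) for fp in fps],
        token_ids=[alphabet.encode(tokenize(s)) for s in smiles],
        processed_1h=np.load(src / "processed_1h.npy"),
        binned_13c=np.load(src / "binned_13c.npy"),
        vocab=vocab,
        alphabet=alphabet,
        manifest=manifest,
    )
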