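"""Canonical SMILES handling, tokenization, substructure fingerprints, similarity.

Molecules are represented throughout the package by their canonical SMILES
string (stereochemistry stripped), produced by RDKit's canonicalizer.
Substructure profiles are binary vectors over an ordered SMARTS vocabulary;
the compact "presence index" form lists the 1-based positions of the set
bits, with index 0 reserved for sequence padding.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import DataStructs
from rdkit.Chem.rdFingerprintGenerator import GetMorganGenerator

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "InvalidMoleculeError",
    "TokenizationError",
    "CanonicalSmiles",
    "TokenAlphabet",
    "SubstructureVocabulary",
    "canonicalize",
    "tokenize",
    "detokenize",
    "build_alphabet",
    "compute_fingerprint",
    "to_presence_indices",
    "from_presence_indices",
    "tanimoto",
    "toy_vocabulary",
    "default_vocabulary",
    "load_vocabulary",
    "save_vocabulary",
]


class InvalidMoleculeError(ValueError):
    """Raised when a SMILES or SMARTS string does not describe a valid pattern."""


class TokenizationError(ValueError):
    """Raised when a SMILES string contains a character outside every lexeme class."""

    def __init__(self, smiles: str, offset: int):
        self.smiles = smiles
        self.offset = offset
        super().__init__(
            f"cannot tokenize {smiles!r}: no SMILES lexeme at offset {offset} "
            f"({smiles[offset:offset + 8]!r})"
        )


# The standard SMILES lexeme regex: bracket atoms, two-letter halogens,
# organic-subset atoms and aromatics, bonds/branches/ring digits, and
# %nn two-digit ring-bond labels.
SMILES_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|N|O|S|P|F|I|B|C|b|c|n|o|s|p"
    r"|\(|\)|\.|=|#|-|\+|\\|/|:|~|@|\?|>|\*|\$|%\d{2}|\d)"
)

PAD, START, STOP = "<pad>", "<start>", "<stop>"
RESERVED_TOKENS = (PAD, START, STOP)


@dataclass(frozen=True)
class CanonicalSmiles:
    """A toolkit-canonical SMILES string (no stereochemistry marks)."""

    text: str

    def __post_init__(self):
        if not self.text:
            raise InvalidMoleculeError("empty SMILES")

    def mol(self) -> Chem.Mol:
        m = Chem.MolFromSmiles(self.text)
        if m is None:  # pragma: no cover - construction guarantees validity
            raise InvalidMoleculeError(f"not a valid molecule: {self.text!r}")
        return m

    @property
    def heavy_atoms(self) -> int:
        return self.mol().GetNumHeavyAtoms()

    def __str__(self) -> str:
        return self.text


def canonicalize(smiles: str) -> CanonicalSmiles:
    """Return the canonical form of ``smiles``, stripping stereochemistry.

    Idempotent: canonicalizing the returned text reproduces it exactly.

    Raises
    ------
    InvalidMoleculeError
        If the string does not parse to a valid molecule.
    """
    if not smiles or not smiles.strip():
        raise InvalidMoleculeError("empty SMILES")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidMoleculeError(f"not a valid molecule: {smiles!r}")
    Chem.RemoveStereochemistry(mol)
    text = Chem.MolToSmiles(mol, canonical=True, isomericSmiles=False)
    # a few exotic aromatic systems canonicalize to strings the parser then
    # rejects (kekulization); treat those as invalid rather than emit a
    # canonical form that cannot round-trip
    if Chem.MolFromSmiles(text) is None:
        raise InvalidMoleculeError(f"canonical form does not re-parse: {smiles!r} -> {text!r}")
    return CanonicalSmiles(text)


def tokenize(smiles: str) -> list[str]:
    """Split a SMILES string into its lexemes.

    Bracket atoms (``[nH]``), two-letter elements (``Cl``/``Br``) and
    ``%nn`` ring-bond labels are single tokens.  Concatenating the result
    reproduces the input exactly.
    """
    tokens: list[str] = []
    pos = 0
    for m in SMILES_TOKEN_RE.finditer(smiles):
        if m.start() != pos:
            raise TokenizationError(smiles, pos)
        tokens.append(m.group())
        pos = m.end()
    if pos != len(smiles):
        raise TokenizationError(smiles, pos)
    return tokens


def detokenize(tokens: Sequence[str]) -> str:
    """Concatenate tokens back into a SMILES string (inverse of :func:`tokenize`)."""
    return "".join(tokens)


@dataclass(frozen=True)
class TokenAlphabet:
    """Ordered token set with reserved PAD (0), START, STOP entries.

    Token order is deterministic: reserved tokens first, then the chemical
    tokens sorted lexicographically, so the same corpus always yields the
    same index mapping.
    """

    tokens: tuple[str, ...]
    _index: dict = field(repr=False, compare=False, default=None)

    def __post_init__(self):
        if self.tokens[: len(RESERVED_TOKENS)] != RESERVED_TOKENS:
            raise ValueError("alphabet must start with PAD, START, STOP")
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("alphabet tokens must be unique")
        object.__setattr__(self, "_index", {t: i for i, t in enumerate(self.tokens)})

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self._index

    @property
    def pad_index(self) -> int:
        return 0

    @property
    def start_index(self) -> int:
        return self._index[START]

    @property
    def stop_index(self) -> int:
        return self._index[STOP]

    def index(self, token: str) -> int:
        try:
            return self._index[token]
        except KeyError:
            raise KeyError(f"token {token!r} not in alphabet") from None

    def encode(self, tokens: Sequence[str]) -> np.ndarray:
        return np.array([self.index(t) for t in tokens], dtype=np.int64)

    def decode(self, indices: Iterable[int]) -> list[str]:
        return [self.tokens[int(i)] for i in indices]

    def content_hash(self) -> str:
        return hashlib.sha256("\n".join(self.tokens).encode()).hexdigest()[:16]


def build_alphabet(corpus: Iterable[CanonicalSmiles | str]) -> TokenAlphabet:
    """Collect the union of tokens over a corpus into a deterministic alphabet."""
    seen: set[str] = set()
    n = 0
    for smi in corpus:
        text = smi.text if isinstance(smi, CanonicalSmiles) else smi
        seen.update(tokenize(text))
        n += 1
    if n == 0:
        raise ValueError("corpus is empty")
    return TokenAlphabet(RESERVED_TOKENS + tuple(sorted(seen)))


@dataclass(frozen=True)
class SubstructureVocabulary:
    """Ordered list of SMARTS patterns defining fingerprint semantics.

    Fingerprint bit *i* records whether pattern *i* matches; the order is
    therefore part of the vocabulary's identity and is captured by
    :meth:`content_hash`.
    """

    patterns: tuple[str, ...]
    name: str = "vocabulary"

    def __post_init__(self):
        for i, p in enumerate(self.patterns):
            if Chem.MolFromSmarts(p) is None:
                raise InvalidMoleculeError(f"invalid SMARTS at index {i}: {p!r}")

    def __len__(self) -> int:
        return len(self.patterns)

    @property
    def size(self) -> int:
        return len(self.patterns)

    def query_mols(self) -> list[Chem.Mol]:
        return [Chem.MolFromSmarts(p) for p in self.patterns]

    def content_hash(self) -> str:
        return hashlib.sha256("\n".join(self.patterns).encode()).hexdigest()[:16]


def compute_fingerprint(
    mol: CanonicalSmiles | str, vocab: SubstructureVocabulary
) -> np.ndarray:
    """Binary presence vector over the vocabulary (1 = at least one match)."""
    m = mol.mol() if isinstance(mol, CanonicalSmiles) else canonicalize(mol).mol()
    bits = np.zeros(len(vocab), dtype=np.int8)
    for i, q in enumerate(vocab.query_mols()):
        if q is None:  # pragma: no cover - vocabulary validates on construction
            raise InvalidMoleculeError(f"invalid SMARTS at index {i}")
        if m.HasSubstructMatch(q):
            bits[i] = 1
    return bits


def to_presence_indices(fp: np.ndarray) -> np.ndarray:
    """1-based, strictly increasing indices of the set bits (0 reserved for padding)."""
    fp = np.asarray(fp)
    return (np.flatnonzero(fp) + 1).astype(np.int64)


def from_presence_indices(indices: Sequence[int], size: int) -> np.ndarray:
    """Scatter presence indices back into a binary vector of length ``size``."""
    bits = np.zeros(size, dtype=np.int8)
    idx = np.asarray(indices, dtype=np.int64)
    if idx.size:
        if idx.min() < 1 or idx.max() > size:
            raise ValueError("presence index out of range")
        bits[idx - 1] = 1
    return bits


_MORGAN = GetMorganGenerator(radius=2, fpSize=2048)


def _morgan_fp(smiles: CanonicalSmiles | str):
    m = smiles.mol() if isinstance(smiles, CanonicalSmiles) else canonicalize(smiles).mol()
    return _MORGAN.GetFingerprint(m)


def tanimoto(a: CanonicalSmiles | str, b: CanonicalSmiles | str) -> float:
    """Tanimoto similarity of Morgan (radius 2, 2048-bit) fingerprints."""
    return float(DataStructs.TanimotoSimilarity(_morgan_fp(a), _morgan_fp(b)))


# --- shipped vocabularies ---------------------------------------------------

_TOY_SMARTS = (
    "[CH3]",        # methyl
    "[CH2]",        # methylene
    "[CH]",         # methine
    "[OX2H]",       # hydroxyl
    "[OX2H0]",      # ether / ester oxygen
    "C=O",          # carbonyl
    "[CX3](=O)[OX2H1]",  # carboxylic acid
    "[CX3](=O)[OX2H0]",  # ester
    "[CX3H1]=O",    # aldehyde
    "[NX3;H2]",     # primary amine
    "[NX3;H1]",     # secondary amine
    "[NX3;H0]",     # tertiary amine
    "C#N",          # nitrile
    "C=C",          # alkene
    "C#C",          # alkyne
    "c",            # aromatic carbon
    "n",            # aromatic nitrogen
    "o",            # aromatic oxygen
    "[R]",          # any ring atom
    "C=N",          # imine
)


def toy_vocabulary() -> SubstructureVocabulary:
    """20 small SMARTS patterns (≤4 atoms) used for tests and toy datasets."""
    return SubstructureVocabulary(_TOY_SMARTS, name="toy-20")


def default_vocabulary() -> SubstructureVocabulary:
    """The shipped default vocabulary of simple C/N/O fragments (≤7 atoms).

    Loaded from ``data/default_vocab.smarts``.  The reference configuration
    uses a 957-pattern set distributed separately; any vocabulary file can
    be plugged in via :func:`load_vocabulary`.
    """
    path = Path(__file__).parent / "data" / "default_vocab.smarts"
    return load_vocabulary(path, name="default-cno")


def load_vocabulary(path: str | Path, name: str | None = None) -> SubstructureVocabulary:
    """Read a one-SMARTS-per-line vocabulary file (``#`` lines are comments)."""
    path = Path(path)
    patterns = [
        line.strip()
        for line in path.read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    if not patterns:
        raise ValueError(f"no SMARTS patterns in {path}")
    return SubstructureVocabulary(tuple(patterns), name=name or path.stem)


def save_vocabulary(vocab: SubstructureVocabulary, path: str | Path) -> None:
    path = Path(path)
    header = f"# {vocab.name}  size={len(vocab)}  sha256:{vocab.content_hash()}\n"
    path.write_text(header + "\n".join(vocab.patterns) + "\n")
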