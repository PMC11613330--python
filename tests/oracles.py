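"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they validate: the subgraph matcher
below uses only RDKit's primitive per-atom / per-bond query ``Match`` calls
with its own backtracking search (never ``GetSubstructMatches``), and the
metric recomputations use plain Python loops.
"""

from __future__ import annotations

import itertools

import numpy as np
from rdkit import Chem


def brute_force_has_match(target: Chem.Mol, query: Chem.Mol) -> bool:
    """Backtracking subgraph-monomorphism search using primitive Match calls."""
    nq = query.GetNumAtoms()
    nt = target.GetNumAtoms()
    if nq > nt:
        return False
    # candidate target atoms for each query atom
    candidates = [
        [t.GetIdx() for t in target.GetAtoms() if qa.Match(t)]
        for qa in query.GetAtoms()
    ]
    if any(not c for c in candidates):
        return False
    q_bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b) for b in query.GetBonds()
    ]

    mapping: dict[int, int] = {}
    used: set[int] = set()

    def extend(qi: int) -> bool:
        if qi == nq:
            return True
        for ti in candidates[qi]:
            if ti in used:
                continue
            ok = True
            for a, b, qbond in q_bonds:
                if b == qi and a in mapping:
                    tb = target.GetBondBetweenAtoms(mapping[a], ti)
                elif a == qi and b in mapping:
                    tb = target.GetBondBetweenAtoms(mapping[b], ti)
                else:
                    continue
                if tb is None or not qbond.Match(tb):
                    ok = False
                    break
            if ok:
                mapping[qi] = ti
                used.add(ti)
                if extend(qi + 1):
                    return True
                del mapping[qi]
                used.remove(ti)
        return False

    return extend(0)


def brute_force_fingerprint(smiles: str, smarts_patterns) -> np.ndarray:
    target = Chem.MolFromSmiles(smiles)
    bits = np.zeros(len(smarts_patterns), dtype=np.int8)
    for i, patt in enumerate(smarts_patterns):
        if brute_force_has_match(target, Chem.MolFromSmarts(patt)):
            bits[i] = 1
    return bits


def brute_force_enumerate_3_carbons() -> set[str]:
    """All distinct ≤3-heavy-atom carbon molecules by exhaustive bond assignment."""
    out: set[str] = set()
    for n in (1, 2, 3):
        pairs = list(itertools.combinations(range(n), 2))
        for orders in itertools.product(range(4), repeat=len(pairs)):
            mol = Chem.RWMol()
            for _ in range(n):
                mol.AddAtom(Chem.Atom("C"))
            for (a, b), o in zip(pairs, orders):
                if o:
                    mol.AddBond(a, b, Chem.BondType.values[o])
            m = mol.GetMol()
            # connected?
            if n > 1:
                adj = Chem.GetAdjacencyMatrix(m)
                reach = {0}
                frontier = [0]
                while frontier:
                    v = frontier.pop()
                    for w in np.flatnonzero(adj[v]):
                        if w not in reach:
                            reach.add(int(w))
                            frontier.append(int(w))
                if len(reach) != n:
                    continue
            try:
                Chem.SanitizeMol(m)
            except Exception:
                continue
            if m.GetRingInfo().NumRings() > 1:
                continue
            out.add(Chem.MolToSmiles(m, canonical=True, isomericSmiles=False))
    return out


def brute_force_bin(peaks, lo: float, hi: float, count: int) -> np.ndarray:
    """Interval-scan binning oracle: test each peak against every bin interval."""
    width = (hi - lo) / count
    bits = np.zeros(count, dtype=np.int8)
    for p in peaks:
        p_eff = min(max(p, lo), hi)  # clamp to range like the implementation
        for j in range(count):
            left = lo + j * width
            right = lo + (j + 1) * width
            in_bin = (left <= p_eff < right) or (j == count - 1 and p_eff == hi)
            if in_bin:
                bits[j] = 1
                break
    return bits
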