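"""Unit tests for molecule enumeration, the toy simulator, and dataset assembly."""

import numpy as np
import pytest
from rdkit import Chem

from nmr2struct import chem, simulate, spectra

from oracles import brute_force_enumerate_3_carbons


def test_enumeration_matches_brute_force_for_carbon_only():
    got = {s.text for s in simulate.enumerate_molecules(3, elements=("C",))}
    want = brute_force_enumerate_3_carbons()
    assert got == want


def test_enumeration_deterministic_and_sorted():
    a = simulate.enumerate_molecules(4)
    b = simulate.enumerate_molecules(4)
    assert [s.text for s in a] == [s.text for s in b]
    keys = [(s.heavy_atoms, s.text) for s in a]
    assert keys == sorted(keys)


def test_enumeration_properties():
    mols = simulate.enumerate_molecules(4)
    assert len(mols) == len({s.text for s in mols})
    for s in mols:
        m = Chem.MolFromSmiles(s.text)
        assert m is not None
        assert m.GetNumHeavyAtoms() <= 4
        assert m.GetRingInfo().NumRings() <= 1
        assert chem.canonicalize(s.text).text == s.text
        for bond in m.GetBonds():
            assert bond.GetBondTypeAsDouble() <= 3.0


def test_enumeration_rejects_bad_args():
    with pytest.raises(ValueError):
        simulate.enumerate_molecules(0)
    with pytest.raises(ValueError):
        simulate.enumerate_molecules(9)
    with pytest.raises(ValueError):
        simulate.enumerate_molecules(3, elements=("C", "Si"))


def test_simulate_1h_integral_tracks_hydrogen_count():
    # unit-integral Lorentzians scaled by H count: total integral ~ n_H
    model = simulate.ShiftModel()
    for smi, n_h in [("CC", 6), ("CO", 4), ("C1CC1", 6)]:
        raw = simulate.simulate_1h(chem.canonicalize(smi), model)
        integral = np.trapezoid(raw.intensities, raw.shifts_ppm)
        assert integral == pytest.approx(n_h, rel=0.05)


def test_simulate_1h_deterministic_and_noise_seeded():
    mol = chem.canonicalize("CCO")
    a = simulate.simulate_1h(mol)
    b = simulate.simulate_1h(mol)
    assert np.array_equal(a.intensities, b.intensities)
    noisy = simulate.ShiftModel(noise_sigma=0.01)
    c = simulate.simulate_1h(mol, noisy)
    d = simulate.simulate_1h(mol, noisy)
    assert np.array_equal(c.intensities, d.intensities)
    assert not np.array_equal(a.intensities, c.intensities)


def test_simulate_1h_ethanol_multiplets():
    # CH3-CH2-OH: methyl couples to 2 H (triplet), methylene to 3 H (quartet)
    mol = chem.canonicalize("CCO")
    raw = simulate.simulate_1h(mol)
    assert raw.intensities.size == 32768
    assert raw.shifts_ppm[0] == pytest.approx(-2.0)
    assert raw.shifts_ppm[-1] == pytest.approx(12.0)
    assert raw.intensities.min() >= 0


def test_simulate_13c_distinct_environments():
    model = simulate.ShiftModel()
    # ethanol: 2 distinct carbons; benzene: 1; acetone: 2
    assert simulate.simulate_13c(chem.canonicalize("CCO"), model).shifts_ppm.size == 2
    assert simulate.simulate_13c(chem.canonicalize("c1ccccc1"), model).shifts_ppm.size == 1
    assert simulate.simulate_13c(chem.canonicalize("CC(C)=O"), model).shifts_ppm.size == 2
    peaks = simulate.simulate_13c(chem.canonicalize("CC(=O)OC"), model).shifts_ppm
    assert np.all(peaks >= spectra.DEFAULT_BINS.lo)
    assert np.all(peaks <= spectra.DEFAULT_BINS.hi)


def test_make_dataset_shapes_and_alignment(tiny_dataset):
    ds = tiny_dataset
    n = len(ds)
    assert ds.processed_1h.shape == (n, 28000)
    assert ds.processed_1h.dtype == np.float32
    assert ds.binned_13c.shape == (n, 80)
    assert ds.fingerprints.shape == (n, len(ds.vocab))
    for i in range(n):
        assert np.array_equal(
            ds.presence_indices[i], chem.to_presence_indices(ds.fingerprints[i])
        )
        assert ds.alphabet.decode(ds.token_ids[i]) == chem.tokenize(ds.smiles[i])
        assert ds.processed_1h[i].max() == pytest.approx(1.0)


def test_make_dataset_drops_hydrogen_free_molecules():
    ds = simulate.make_dataset(["CCO", "O=C=O"])
    assert len(ds) == 1
    assert ds.manifest["n_dropped_no_hydrogen"] == 1


def test_dataset_save_load_round_trip(tiny_dataset, tmp_path):
    simulate.save_dataset(tiny_dataset, tmp_path / "ds")
    back = simulate.load_dataset(tmp_path / "ds")
    assert back.smiles == tiny_dataset.smiles
    assert back.alphabet.tokens == tiny_dataset.alphabet.tokens
    assert back.vocab.patterns == tiny_dataset.vocab.patterns
    assert np.array_equal(back.fingerprints, tiny_dataset.fingerprints)
    assert np.allclose(back.processed_1h, tiny_dataset.processed_1h)
    assert np.array_equal(back.binned_13c, tiny_dataset.binned_13c)
    for a, b in zip(back.token_ids, tiny_dataset.token_ids):
        assert np.array_equal(a, b)


def test_dataset_subset(tiny_dataset):
    sub = tiny_dataset.subset([2, 0])
    assert sub.smiles == [tiny_dataset.smiles[2], tiny_dataset.smiles[0]]
    assert np.array_equal(sub.processed_1h[1], tiny_dataset.processed_1h[0])
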