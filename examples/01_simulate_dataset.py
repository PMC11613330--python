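"""Build a small simulated NMR dataset from enumerated molecules.

Enumerates every C/N/O molecule with at most 4 heavy atoms, simulates its
1H and 13C spectra, computes substructure profiles against the toy
vocabulary, and saves everything to ``example_data/``.

Run from the repository root:  python examples/01_simulate_dataset.py
"""

import numpy as np

from nmr2struct import chem, simulate, spectra

# 1. Enumerate the chemical space: trees + single rings over C/N/O.
molecules = simulate.enumerate_molecules(max_heavy=4)
print(f"enumerated {len(molecules)} molecules with <=4 heavy atoms")
print("first five:", [m.text for m in molecules[:5]])

# 2. Simulate one molecule by hand to see the pieces.
ethanol = chem.canonicalize("CCO")
raw = simulate.simulate_1h(ethanol)
processed = spectra.preprocess_1h(raw)
print(f"\nethanol 1H: raw {raw.shifts_ppm.size} points -> grid {processed.size} points")
print(f"  integral ~ n_H: {np.trapezoid(raw.intensities, raw.shifts_ppm):.2f} (6 H)")

peaks = simulate.simulate_13c(ethanol)
bins = spectra.bin_13c(peaks, spectra.DEFAULT_BINS)
print(f"ethanol 13C: {peaks.shifts_ppm.size} distinct carbons -> {int(bins.sum())} occupied bins")

profile = chem.compute_fingerprint(ethanol, chem.toy_vocabulary())
print(f"substructure profile: {int(profile.sum())}/{profile.size} patterns present")

# 3. Build and save the full dataset (drops H-free molecules).
ds = simulate.make_dataset(molecules, out_dir="example_data")
print(f"\ndataset: {len(ds)} records saved to example_data/")
print(f"  processed 1H block: {ds.processed_1h.shape} float32")
print(f"  binned 13C block:   {ds.binned_13c.shape} int8")
print(f"  alphabet: {len(ds.alphabet)} tokens, vocabulary: {len(ds.vocab)} patterns")
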