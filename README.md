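# nmr2struct

Multitask machine learning for small-molecule structure elucidation from
1D NMR: predict a molecule's **substructure profile** and its **SMILES
structure** directly from ¹H and/or ¹³C spectra.

Everything runs on plain NumPy + RDKit on a single CPU core — the
transformer, its training loop, and a small reverse-mode autograd engine
are part of the package (`nmr2struct.nets`), so there is no deep-learning
framework dependency.

## The idea

Spectroscopists read an NMR spectrum in two steps: first they spot
functional groups ("a triplet near 1.2 ppm, an OH, an ester carbonyl"),
then they assemble those fragments into a structure.  The package mirrors
this:

1. **Substructure → structure pretraining.**  A transformer
   encoder–decoder learns to emit SMILES token-by-token from the set of
   SMARTS substructures the molecule contains.  The encoder treats the
   profile as a *set* (no positional encoding); the decoder is a standard
   causal transformer.
2. **Spectrum → (substructures, structure) multitask training.**  The
   pretrained encoder/decoder weights initialize a multitask model whose
   input frontends read spectra instead: a strided 1-D CNN over the
   28 000-point processed ¹H grid, and learned embeddings of the 80
   binary ¹³C presence bins.  It jointly predicts per-substructure
   probabilities (sigmoid head) and the SMILES sequence.

Structure predictions are drawn by top-k sampling (k = 5, 15 samples per
spectrum) and scored by canonical-SMILES match ("top-15 accuracy"),
micro-F1 of the substructure head, probability calibration, and Morgan
Tanimoto similarity of near misses.

Since real assigned spectra cannot be shipped with the package, a
first-order forward simulator (exhaustive C/N/O molecule enumeration,
increment-rule shifts, first-order multiplets) generates fully seeded
datasets on the fly.  See `docs/methods.md` for the model, simulator
limitations, and the reference problem sizes (all chosen so the complete
test suite and acceptance run stay in the minutes range on one core).

## Worked example

Simulate a dataset, pretrain on substructure profiles, transfer to the
multitask spectrum model, and evaluate — the library version of the
two-stage pipeline (also available as `examples/02_pretrain_and_transfer.py`):

```python
from nmr2struct import chem, evaluate, simulate, train
from nmr2struct.nets import (TransformerConfig, MultitaskConfig,
                             build_substruct2struct, build_multitask,
                             transfer_weights)

mols = simulate.enumerate_molecules(4)          # all C/N/O molecules, <=4 heavy atoms
ds = simulate.make_dataset(mols, vocab=chem.default_vocabulary())
tr, va, te = train.split_dataset(len(ds),
                                 train.SplitSpec(train=0.7, val=0.2, test=0.1, seed=0))

cfg = TransformerConfig(d_model=48, n_heads=4, n_encoder_layers=2,
                        n_decoder_layers=2, d_ff=96,
                        alphabet_size=len(ds.alphabet), vocab_size=len(ds.vocab))

s2s = build_substruct2struct(cfg, seed=0)       # stage 1: substructures -> SMILES
train.fit(s2s, ds, tr, va,
          train.TrainSchedule(epochs=40, batch_size=32, lr=2e-3, patience=6, seed=0))

mt = build_multitask(MultitaskConfig(transformer=cfg,
                                     cnn_channels=(16, 32, 48),
                                     cnn_kernels=(14, 8, 7),
                                     cnn_strides=(14, 8, 7)), seed=0)
transfer_weights(s2s, mt)                       # stage 2: spectra -> both tasks
train.fit(mt, ds, tr, va,
          train.TrainSchedule(epochs=30, batch_size=32, lr=1.5e-3, patience=5, seed=0))

report = evaluate.evaluate_model(mt, ds, va, seed=0)
print(report.top_n_accuracy, report.f1["f1"])
```

Running the example script prints (one CPU core, ~2.5 min):

```text
$ python examples/02_pretrain_and_transfer.py
dataset 496 records; split 347/99/50
stage 1: 34 epochs, val loss 0.390, val top-15 accuracy 0.71
stage 2: 16 epochs, val loss 1.143, val top-15 accuracy 0.19, substructure F1 0.21
calibration: {'accuracy_low': 0.9854662898667743, 'accuracy_high': None, 'fraction_mid': 0.19935353535353537}
tanimoto of near misses: {'n': 80, 'n_omitted': 0, 'fraction_ge_0.5': 0.0375, 'mean': 0.24922958985458984}
```

Reading the numbers: given only ground-truth substructure profiles, the
pretrained decoder recovers 71 % of held-out structures; reading raw
simulated spectra instead, the transfer-initialized multitask model
recovers 19 % — far above the ~0.2 % chance level for this space, and
with its low-probability substructure calls 99 % correct.  These are
small-scale reference numbers, not the large-data regime; see
`docs/methods.md`.

The same pipeline is available from the command line
(`examples/03_cli_workflow.sh` runs it end to end):

```sh
nmr2struct simulate --max-heavy 4 --vocab toy --out data/
nmr2struct pretrain --dataset data/ --out s2s.json
nmr2struct train --dataset data/ --init-from s2s.json --modality both --out mt.json
nmr2struct evaluate --checkpoint mt.json --dataset data/ --split test --out report.json
nmr2struct predict --checkpoint mt.json --h1 spectrum.csv --c13 peaks.csv
```

## Reference benchmarks

`nmr2struct.benchmarks` pins down two seeded reference experiments
(shared by the tests and the acceptance script):

- **Memorization** — a 200-molecule fixture the substructure-to-structure
  model must fit to ≥95 % top-15 training accuracy within 50 epochs, and
  the transfer-initialized multitask model to ≥70 %.
- **Directional** — the full 520-molecule ≤4-heavy-atom space
  (70/20/10 split) checking, over 3 seeds with every arm trained to
  convergence, that transfer initialization does not hurt median
  validation accuracy and that a ¹H-only model is at least as accurate
  as a ¹³C-only model.  At this reference scale the first holds (median
  0.192 with transfer vs 0.182 random) but the second currently does
  **not** (median 0.121 ¹H vs 0.152 ¹³C): with ~350 training molecules
  the hand-discretized ¹³C bins are more sample-efficient than a CNN
  that must learn ¹H feature extraction from 28 000 raw points.  The
  corresponding acceptance test is left failing honestly rather than
  tuned away; the analysis is in `docs/methods.md`.

## Repository layout

```
src/nmr2struct/
  chem.py        SMILES canonicalization, tokenizer, SMARTS vocabularies,
                 fingerprints, Tanimoto
  spectra.py     1H grid processing, 13C binning, CSV/JCAMP-DX I/O
  simulate.py    molecule enumeration, forward NMR simulator, dataset builder
  nets/          autograd engine, transformer, multitask model, checkpoints
  train.py       splits, batching, losses, Adam, fit loop
  evaluate.py    top-k sampling, accuracy/F1/calibration/Tanimoto metrics
  benchmarks.py  the seeded reference experiments
  cli.py         `nmr2struct` command-line interface
docs/methods.md  models, simulator, numerical choices, problem sizes
examples/        narrative scripts
tests/           pytest suite incl. acceptance tests and independent oracles
scripts/         acceptance.py
```
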