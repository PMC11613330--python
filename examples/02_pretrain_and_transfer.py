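"""Two-stage training: pretrain on substructures, transfer to spectra.

Stage 1 trains a substructure-to-structure transformer (ground-truth
profiles in, SMILES out).  Stage 2 copies its encoder/decoder weights
into a multitask model that reads simulated spectra and predicts both the
substructure profile and the SMILES string.

Uses the full enumerated <=4-heavy-atom space (496 molecules with
hydrogens) so the validation numbers sit well above the floor; see
docs/methods.md for why dense coverage of a small space is the package's
reference regime.

Run from the repository root:  python examples/02_pretrain_and_transfer.py
(takes a couple of minutes on one CPU core)
"""

from nmr2struct import chem, evaluate, simulate, train
from nmr2struct.nets import (
    MultitaskConfig,
    TransformerConfig,
    build_multitask,
    build_substruct2struct,
    transfer_weights,
)

mols = simulate.enumerate_molecules(4)
ds = simulate.make_dataset(mols, vocab=chem.default_vocabulary())
tr, va, te = train.split_dataset(len(ds), train.SplitSpec(train=0.7, val=0.2, test=0.1, seed=0))
print(f"dataset {len(ds)} records; split {len(tr)}/{len(va)}/{len(te)}")

cfg = TransformerConfig(
    d_model=48, n_heads=4, n_encoder_layers=2, n_decoder_layers=2,
    d_ff=96, alphabet_size=len(ds.alphabet), vocab_size=len(ds.vocab),
)

# Stage 1: substructure profile -> structure.
s2s = build_substruct2struct(cfg, seed=0)
fit1 = train.fit(s2s, ds, tr, va,
                 train.TrainSchedule(epochs=40, batch_size=32, lr=2e-3, patience=6, seed=0))
rep1 = evaluate.evaluate_model(s2s, ds, va, seed=0)
print(f"stage 1: {len(fit1.history)} epochs, val loss {fit1.best_val_loss:.3f}, "
      f"val top-15 accuracy {rep1.top_n_accuracy:.2f}")

# Stage 2: spectra -> (profile, structure), initialized from stage 1.
mcfg = MultitaskConfig(
    transformer=cfg,
    cnn_channels=(16, 32, 48), cnn_kernels=(14, 8, 7), cnn_strides=(14, 8, 7),
)
mt = build_multitask(mcfg, seed=0)
transfer_weights(s2s, mt)
fit2 = train.fit(mt, ds, tr, va,
                 train.TrainSchedule(epochs=30, batch_size=32, lr=1.5e-3, patience=5, seed=0))
rep2 = evaluate.evaluate_model(mt, ds, va, seed=0)
print(f"stage 2: {len(fit2.history)} epochs, val loss {fit2.best_val_loss:.3f}, "
      f"val top-15 accuracy {rep2.top_n_accuracy:.2f}, "
      f"substructure F1 {rep2.f1['f1']:.2f}")
print(f"calibration: {rep2.calibration}")
print(f"tanimoto of near misses: {rep2.tanimoto_summary}")
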