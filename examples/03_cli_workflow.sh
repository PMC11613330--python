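#!/bin/sh
# End-to-end command-line workflow: simulate a dataset, pretrain, transfer,
# predict, evaluate.  Run from the repository root; writes under ./cli_demo.
set -e

# 1. Simulate a dataset (<=4 heavy atoms, toy vocabulary).
nmr2struct simulate --max-heavy 4 --vocab toy --seed 0 --out cli_demo/data

# 2. Pretrain the substructure-to-structure model.
nmr2struct pretrain --dataset cli_demo/data --epochs 20 --batch-size 16 \
    --lr 2e-3 --d-model 48 --d-ff 96 --out cli_demo/s2s.json

# 3. Train the multitask model from the pretrained weights.
nmr2struct train --dataset cli_demo/data --init-from cli_demo/s2s.json \
    --modality both --epochs 10 --batch-size 16 --lr 1.5e-3 \
    --d-model 48 --d-ff 96 --out cli_demo/mt.json

# 4. Evaluate on the held-out test split (JSON report).
nmr2struct evaluate --checkpoint cli_demo/mt.json --dataset cli_demo/data \
    --split test --out cli_demo/report.json

# 5. Predict structures for one simulated spectrum pair (ethanol).
python - <<'EOF'
from nmr2struct import chem, simulate, spectra
mol = chem.canonicalize("CCO")
spectra.write_csv_1h("cli_demo/ethanol_h1.csv", simulate.simulate_1h(mol))
spectra.write_csv_13c("cli_demo/ethanol_c13.csv", simulate.simulate_13c(mol))
EOF
nmr2struct predict --checkpoint cli_demo/mt.json \
    --h1 cli_demo/ethanol_h1.csv --c13 cli_demo/ethanol_c13.csv \
    --k 5 --n-samples 15 --out cli_demo/predictions.tsv
cat cli_demo/predictions.tsv

cat cli_demo/report.json
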