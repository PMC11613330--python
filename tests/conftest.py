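"""Shared fixtures.

Expensive artifacts (datasets, trained models) are session-scoped so the
unit tests and the acceptance tests reuse a single instance.  Everything is
seeded; no fixture depends on the network or on files outside the repo.
"""

import pytest

from nmr2struct import benchmarks, simulate


@pytest.fixture(scope="session")
def tiny_dataset():
    """~40 molecules (≤3 heavy atoms, toy vocabulary): fast unit-test data."""
    mols = simulate.enumerate_molecules(3)
    return simulate.make_dataset(mols)


@pytest.fixture(scope="session")
def memo_dataset():
    """The seeded 200-molecule memorization fixture (≤5 heavy, default vocab)."""
    return benchmarks.memorization_dataset()


@pytest.fixture(scope="session")
def s2s_memo(memo_dataset):
    """Substructure-to-structure model memorizing the 200-molecule fixture."""
    return benchmarks.fit_memorization_s2s(memo_dataset, seed=0)


@pytest.fixture(scope="session")
def mt_memo(memo_dataset, s2s_memo):
    """Multitask model (transfer-initialized) memorizing the same fixture."""
    return benchmarks.fit_memorization_multitask(memo_dataset, s2s_memo[0], seed=0)


@pytest.fixture(scope="session")
def directional_results():
    """Validation accuracies of the transfer/modality benchmark, 3 seeds.

    Returns {config_name: [accuracy per seed]} for the four configurations
    {both+transfer, both+random, h1+transfer, c13+transfer}.
    """
    from nmr2struct import evaluate

    ds = benchmarks.directional_dataset()
    _, va, _ = benchmarks.directional_split(ds)
    pretrained, _ = benchmarks.fit_directional_s2s(ds, seed=0)
    out = {"both_transfer": [], "both_random": [], "h1_transfer": [], "c13_transfer": []}
    for seed in (0, 1, 2):
        for name, modality, transfer in (
            ("both_transfer", "both", True),
            ("both_random", "both", False),
            ("h1_transfer", "h1", True),
            ("c13_transfer", "c13", True),
        ):
            model, _ = benchmarks.directional_run(ds, pretrained, modality, transfer, seed)
            rep = evaluate.evaluate_model(model, ds, va, seed=0)
            out[name].append(rep.top_n_accuracy)
    return out
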