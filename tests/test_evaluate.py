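"""Tests for sampling behavior and the evaluation metric suite."""

import numpy as np
import pytest

from nmr2struct import evaluate
from nmr2struct.evaluate import (
    PredictionSet,
    best_incorrect_tanimoto,
    calibration_report,
    is_correct,
    problem_size_fit,
    substructure_f1,
    topn_accuracy,
    _sample_step,
)


def test_prediction_set_validity_flags():
    p = PredictionSet(0, ["CCO", "C(((", "OCC", "xyz"])
    assert p.valid == [True, False, True, False]
    assert p.canonical[0] == p.canonical[2] == "CCO"
    assert p.canonical[1] is None


def test_is_correct_uses_canonical_equality():
    p = PredictionSet(0, ["OCC"])
    assert is_correct(p, "CCO")
    assert not is_correct(p, "CCN")
    assert not is_correct(PredictionSet(0, ["bad"]), "CCO")


def test_topn_accuracy_and_grouping():
    preds = [PredictionSet(0, ["CCO"]), PredictionSet(1, ["CCC"]), PredictionSet(2, ["bad"])]
    targets = ["CCO", "CCN", "CO"]
    acc, by_size = topn_accuracy(preds, targets, heavy_atoms=[3, 3, 2])
    assert acc == pytest.approx(1 / 3)
    assert by_size == {2: 0.0, 3: 0.5}
    with pytest.raises(ValueError):
        topn_accuracy(preds, targets[:2])


def test_best_incorrect_tanimoto_excludes_correct_and_invalid():
    preds = [
        PredictionSet(0, ["CCO"]),          # correct -> excluded
        PredictionSet(1, ["CCO", "bad"]),   # incorrect, one valid candidate
        PredictionSet(2, ["bad", "C((("]),  # incorrect, no valid candidate -> omitted
    ]
    targets = ["CCO", "CCN", "CO"]
    sims, summary = best_incorrect_tanimoto(preds, targets)
    assert len(sims) == 1
    assert summary["n"] == 1 and summary["n_omitted"] == 1
    assert 0.0 <= sims[0] < 1.0
    assert summary["mean"] == pytest.approx(sims[0])


def test_substructure_f1_against_brute_force():
    rng = np.random.default_rng(0)
    for _ in range(1000):
        n, v = rng.integers(1, 6), rng.integers(1, 8)
        probs = rng.random((n, v))
        truth = rng.random((n, v)) < 0.4
        got = substructure_f1(probs, truth)
        tp = fp = fn = 0
        for i in range(n):
            for j in range(v):
                pred = probs[i, j] >= 0.5
                if pred and truth[i, j]:
                    tp += 1
                elif pred:
                    fp += 1
                elif truth[i, j]:
                    fn += 1
        want = 1.0 if tp + fp + fn == 0 else 2 * tp / (2 * tp + fp + fn)
        assert got["f1"] == pytest.approx(want)
        assert got["tp"] == tp and got["fp"] == fp and got["fn"] == fn


def test_substructure_f1_empty_convention():
    assert substructure_f1(np.zeros((2, 3)), np.zeros((2, 3)))["f1"] == 1.0


def test_calibration_report_bands():
    probs = np.array([0.01, 0.05, 0.5, 0.95, 0.99, 0.1, 0.9])
    truth = np.array([0, 1, 1, 1, 1, 0, 0])
    rep = calibration_report(probs, truth)
    assert rep["accuracy_low"] == pytest.approx(0.5)     # 0.01 (y=0 ok), 0.05 (y=1 wrong)
    assert rep["accuracy_high"] == pytest.approx(1.0)    # 0.95, 0.99 both y=1
    assert rep["fraction_mid"] == pytest.approx(3 / 7)   # 0.5 and boundary 0.1, 0.9
    none_rep = calibration_report(np.array([0.5]), np.array([1]))
    assert none_rep["accuracy_low"] is None
    assert none_rep["accuracy_high"] is None


def test_problem_size_fit_recovers_exact_exponential():
    counts = {3: 10.0, 4: 100.0, 5: 1000.0}
    predict = problem_size_fit(counts)
    assert predict([6])[0] == pytest.approx(10000.0, rel=1e-6)
    assert predict([3])[0] == pytest.approx(10.0, rel=1e-6)
    with pytest.raises(ValueError):
        problem_size_fit({3: 10.0})
    with pytest.raises(ValueError):
        problem_size_fit({3: 0.0, 4: 1.0})


def test_sample_step_k1_is_argmax_and_never_pad():
    rng = np.random.default_rng(0)
    logits = rng.standard_normal((64, 9))
    choice = _sample_step(logits, k=1, rng=rng, forbidden=[0])
    masked = logits.copy()
    masked[:, 0] = -np.inf
    assert np.array_equal(choice, masked.argmax(axis=1))
    assert np.all(choice != 0)


def test_sample_step_respects_topk_support():
    rng = np.random.default_rng(1)
    logits = np.tile(np.arange(10.0), (200, 1))
    choice = _sample_step(logits, k=3, rng=rng, forbidden=[0])
    assert set(np.unique(choice)) <= {7, 8, 9}


def test_sample_topk_seeded_and_shaped(s2s_memo, memo_dataset):
    model, _ = s2s_memo
    ds = memo_dataset
    src = np.zeros((4, max(len(p) for p in ds.presence_indices[:4])), dtype=np.int64)
    for r in range(4):
        src[r, : len(ds.presence_indices[r])] = ds.presence_indices[r]
    a = evaluate.sample_topk(model, src=src, alphabet=ds.alphabet, seed=3)
    b = evaluate.sample_topk(model, src=src, alphabet=ds.alphabet, seed=3)
    c = evaluate.sample_topk(model, src=src, alphabet=ds.alphabet, seed=4)
    assert len(a) == 4 and all(len(p.samples) == 15 for p in a)
    assert all(pa.samples == pb.samples for pa, pb in zip(a, b))
    assert any(pa.samples != pc.samples for pa, pc in zip(a, c))
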