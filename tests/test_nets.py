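"""Tests for the autograd engine, transformer stacks, transfer and checkpoints."""

import numpy as np
import pytest

from nmr2struct.nets import (
    Multitask,
    MultitaskConfig,
    Substruct2Struct,
    Tensor,
    TransferError,
    TransformerConfig,
    build_from_checkpoint,
    build_multitask,
    build_substruct2struct,
    load_checkpoint,
    save_checkpoint,
    transfer_weights,
)
from nmr2struct.nets import autograd
from nmr2struct.nets.autograd import conv1d, cross_entropy_masked, layer_norm, no_grad


SMALL = TransformerConfig(
    d_model=16, n_heads=2, n_encoder_layers=1, n_decoder_layers=1,
    d_ff=32, alphabet_size=10, vocab_size=8, max_src_len=16, max_tgt_len=16,
)
SMALL_MT = MultitaskConfig(
    transformer=SMALL, cnn_channels=(4, 8), cnn_kernels=(10, 6),
    cnn_strides=(10, 6), h1_length=600, n_bins_13c=12,
)


def _numeric_grad(f, x, eps=1e-3):
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        hi = f()
        x[i] = orig - eps
        lo = f()
        x[i] = orig
        g[i] = (hi - lo) / (2 * eps)
    return g


def test_grad_matmul_and_softmax():
    rng = np.random.default_rng(0)
    a = Tensor(rng.standard_normal((3, 4)).astype(np.float32), requires_grad=True)
    b = Tensor(rng.standard_normal((4, 5)).astype(np.float32), requires_grad=True)
    out = (a @ b).softmax(axis=-1).sum()
    out.backward()
    num = _numeric_grad(lambda: float(((Tensor(a.data) @ Tensor(b.data)).softmax(axis=-1).sum()).data), a.data)
    assert np.allclose(a.grad, num, atol=2e-2)


def test_grad_layer_norm():
    rng = np.random.default_rng(1)
    x = Tensor(rng.standard_normal((2, 3, 8)).astype(np.float32), requires_grad=True)
    gamma = Tensor(np.ones(8, dtype=np.float32), requires_grad=True)
    beta = Tensor(np.zeros(8, dtype=np.float32), requires_grad=True)
    w = rng.standard_normal((2, 3, 8)).astype(np.float32)
    (layer_norm(x, gamma, beta) * Tensor(w)).sum().backward()
    num = _numeric_grad(
        lambda: float((layer_norm(Tensor(x.data), Tensor(gamma.data), Tensor(beta.data)) * Tensor(w)).sum().data),
        x.data,
    )
    assert np.allclose(x.grad, num, atol=2e-2)


def test_grad_conv1d():
    rng = np.random.default_rng(2)
    x = Tensor(rng.standard_normal((2, 20, 3)).astype(np.float32), requires_grad=True)
    w = Tensor(rng.standard_normal((5 * 3, 4)).astype(np.float32), requires_grad=True)
    b = Tensor(np.zeros(4, dtype=np.float32), requires_grad=True)
    conv1d(x, w, b, stride=3).sum().backward()
    num = _numeric_grad(
        lambda: float(conv1d(Tensor(x.data), Tensor(w.data), Tensor(b.data), stride=3).sum().data),
        x.data,
    )
    assert np.allclose(x.grad, num, atol=2e-2)


def test_grad_cross_entropy_masked():
    rng = np.random.default_rng(3)
    logits = Tensor(rng.standard_normal((2, 4, 6)).astype(np.float32), requires_grad=True)
    targets = rng.integers(0, 6, size=(2, 4))
    mask = np.array([[1, 1, 1, 0], [1, 1, 0, 0]], dtype=np.float32)
    cross_entropy_masked(logits, targets, mask).backward()
    num = _numeric_grad(
        lambda: float(cross_entropy_masked(Tensor(logits.data), targets, mask).data),
        logits.data,
    )
    assert np.allclose(logits.grad, num, atol=2e-2)


def test_no_grad_builds_no_graph():
    x = Tensor(np.ones(3, dtype=np.float32), requires_grad=True)
    with no_grad():
        y = (x * 2.0).sum()
    assert not y.requires_grad
    assert y._parents == ()
    z = (x * 2.0).sum()
    assert z.requires_grad


def test_seeded_initialization_is_deterministic():
    m1 = build_substruct2struct(SMALL, seed=5)
    m2 = build_substruct2struct(SMALL, seed=5)
    m3 = build_substruct2struct(SMALL, seed=6)
    s1, s2, s3 = m1.state_dict(), m2.state_dict(), m3.state_dict()
    assert all(np.array_equal(s1[k], s2[k]) for k in s1)
    assert any(not np.array_equal(s1[k], s3[k]) for k in s1)


def test_src_padding_invariance():
    model = build_substruct2struct(SMALL, seed=0).eval()
    src = np.array([[1, 3, 5]])
    src_padded = np.array([[1, 3, 5, 0, 0]])
    tgt = np.array([[1, 4, 2]])
    a = model(src, tgt).data
    b = model(src_padded, tgt).data
    assert np.allclose(a, b, atol=1e-5)


def test_tgt_padding_invariance_across_batch():
    model = build_substruct2struct(SMALL, seed=0).eval()
    src = np.array([[1, 3, 5], [2, 4, 0]])
    tgt_short = np.array([[1, 4, 2]])
    tgt_batch = np.array([[1, 4, 2, 0, 0], [1, 5, 6, 7, 2]])
    solo = model(src[:1], tgt_short).data
    batched = model(src, tgt_batch).data
    assert np.allclose(solo[0], batched[0, :3], atol=1e-5)


def test_decoder_causality():
    model = build_substruct2struct(SMALL, seed=0).eval()
    src = np.array([[1, 3, 5]])
    tgt = np.array([[1, 4, 5, 6, 7]])
    base = model(src, tgt).data
    for t in range(1, 5):
        mutated = tgt.copy()
        mutated[0, t] = 8
        out = model(src, mutated).data
        assert np.allclose(base[0, :t], out[0, :t], atol=1e-5), f"position {t} leaks"


def test_incremental_decoder_matches_full_decode():
    from nmr2struct.nets.transformer import IncrementalDecoder

    model = build_substruct2struct(SMALL, seed=0).eval()
    src = np.array([[1, 3, 5, 0], [2, 4, 6, 7]])
    tgt = np.array([[1, 4, 5, 6, 7, 3], [1, 5, 6, 7, 3, 4]])
    memory, pad = model.encode(src)
    full = model.decode(memory, pad, tgt).data
    dec = IncrementalDecoder(model, memory.data, pad)
    for t in range(tgt.shape[1]):
        step_logits = dec.step(tgt[:, t])
        assert np.allclose(step_logits, full[:, t, :], atol=1e-4), f"step {t}"


def test_multitask_feature_length_property():
    model = build_multitask(SMALL_MT, seed=0).eval()
    h1 = np.random.default_rng(0).random((2, SMALL_MT.h1_length)).astype(np.float32)
    c13 = np.zeros((2, SMALL_MT.n_bins_13c), dtype=np.int8)
    feats = model.features(h1, c13)
    assert feats.shape == (2, SMALL_MT.feature_length, SMALL.d_model)


def test_multitask_modality_contract():
    h1 = np.zeros((1, SMALL_MT.h1_length), dtype=np.float32)
    c13 = np.zeros((1, SMALL_MT.n_bins_13c), dtype=np.int8)
    tgt = np.array([[1, 4]])
    h1_only = build_multitask(
        MultitaskConfig(**{**SMALL_MT.__dict__, "modality": "h1"}), seed=0).eval()
    with pytest.raises(ValueError):
        h1_only(h1, c13, tgt)
    with pytest.raises(ValueError):
        h1_only(None, c13, tgt)
    c13_only = build_multitask(
        MultitaskConfig(**{**SMALL_MT.__dict__, "modality": "c13"}), seed=0).eval()
    with pytest.raises(ValueError):
        c13_only(h1, None, tgt)
    both = build_multitask(SMALL_MT, seed=0).eval()
    with pytest.raises(ValueError):
        both(h1, None, tgt)
    logits, probs, _ = both(h1 + 0.5, c13, tgt)
    assert logits.shape == (1, 2, SMALL.alphabet_size)
    assert probs.shape == (1, SMALL.vocab_size)
    assert np.all((probs.data > 0) & (probs.data < 1))


def test_transfer_weights_contract():
    s2s = build_substruct2struct(SMALL, seed=1)
    mt = build_multitask(SMALL_MT, seed=2)
    before = {k: v.copy() for k, v in mt.state_dict().items()}
    names = transfer_weights(s2s, mt)
    src_state = s2s.state_dict()
    tgt_state = mt.state_dict()
    assert names
    for name in names:
        assert np.array_equal(tgt_state[name], src_state[name])
    for name in tgt_state:
        if name not in names:
            assert np.array_equal(tgt_state[name], before[name]), name
    untouched = [n for n in tgt_state if n.startswith(("cnn.", "substruct_", "c13_", "h1_proj."))]
    assert untouched and not set(untouched) & set(names)


def test_transfer_weights_shape_mismatch():
    wide = TransformerConfig(**{**SMALL.__dict__, "d_model": 32, "n_heads": 2})
    s2s = build_substruct2struct(wide, seed=0)
    mt = build_multitask(SMALL_MT, seed=0)
    with pytest.raises(TransferError):
        transfer_weights(s2s, mt)


def test_checkpoint_round_trip(tmp_path):
    model = build_substruct2struct(SMALL, seed=3).eval()
    alphabet = tuple(f"t{i}" for i in range(SMALL.alphabet_size))
    path = tmp_path / "model.npz"
    save_checkpoint(path, model, alphabet, vocab_hash="abc123", manifest={"note": "test"})
    ckpt = load_checkpoint(path)
    assert ckpt.kind == "substruct2struct"
    assert ckpt.alphabet_tokens == alphabet
    rebuilt = build_from_checkpoint(ckpt, expected_alphabet=alphabet, expected_vocab_hash="abc123")
    src = np.array([[1, 2, 3]])
    tgt = np.array([[1, 4, 5]])
    assert np.allclose(model(src, tgt).data, rebuilt(src, tgt).data, atol=1e-6)
    with pytest.raises(ValueError):
        build_from_checkpoint(ckpt, expected_vocab_hash="wrong")
    with pytest.raises(ValueError):
        build_from_checkpoint(ckpt, expected_alphabet=alphabet[:-1])


def test_multitask_checkpoint_round_trip(tmp_path):
    model = build_multitask(SMALL_MT, seed=4).eval()
    path = tmp_path / "mt.npz"
    save_checkpoint(path, model, ("a", "b"), vocab_hash="h")
    rebuilt = build_from_checkpoint(load_checkpoint(path))
    assert isinstance(rebuilt, Multitask)
    h1 = np.random.default_rng(1).random((1, SMALL_MT.h1_length)).astype(np.float32)
    c13 = np.zeros((1, SMALL_MT.n_bins_13c), dtype=np.int8)
    tgt = np.array([[1, 2]])
    a = model(h1, c13, tgt)
    b = rebuilt(h1, c13, tgt)
    assert np.allclose(a[0].data, b[0].data, atol=1e-6)
    assert np.allclose(a[1].data, b[1].data, atol=1e-6)


def test_load_state_dict_validates():
    model = build_substruct2struct(SMALL, seed=0)
    state = model.state_dict()
    bad = dict(state)
    bad.pop(next(iter(bad)))
    with pytest.raises(ValueError):
        model.load_state_dict(bad)
    bad = dict(state)
    first = next(iter(bad))
    bad[first] = np.zeros((1, 1), dtype=np.float32)
    with pytest.raises(ValueError):
        model.load_state_dict(bad)
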