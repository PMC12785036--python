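"""Encoder forward pass, attention masking, and gradient correctness.

The dense oracle below is an independent plain-NumPy re-derivation of
the forward pass with full (unmasked) attention; on inputs short
enough that the local window covers every pair, the sparse model must
agree with it to float precision.
"""

import numpy as np
import pytest
from scipy.special import erf

from tewick import autograd as ag
from tewick.encoder import (ModelConfig, ModelConfigError,
                            SparseAttentionEncoder, attention_rollback,
                            load_checkpoint, positional_encoding,
                            save_checkpoint, softmax)
from tewick.tokenizer import build_vocabulary, tokenize


def small_config(**overrides) -> ModelConfig:
    base = dict(num_classes=4, kmer_size=3, embedding_dim=16,
                num_hidden_layers=2, num_attention_heads=2,
                intermediate_size=24, max_embeddings=64,
                local_attention_window=16, global_att_tokens=(0,),
                dropout=0.0, seed=9)
    base.update(overrides)
    return ModelConfig(**base)


# -- independent dense-attention oracle --------------------------------------


def _layer_norm_np(x, g, b, eps=1e-5):
    mu = x.mean(-1, keepdims=True)
    var = x.var(-1, keepdims=True)
    return (x - mu) / np.sqrt(var + eps) * g + b


def dense_forward_oracle(model: SparseAttentionEncoder,
                         ids: np.ndarray) -> np.ndarray:
    """Full-attention forward with the model's own weights, no masking."""
    cfg = model.config
    p = {k: v.data.astype(np.float64) for k, v in model.params.items()}
    b, t = ids.shape
    h, dh = cfg.num_attention_heads, cfg.head_dim
    x = p["tok_emb"][ids] + positional_encoding(t, cfg.embedding_dim)
    for layer in range(cfg.num_hidden_layers):
        pre = f"layer{layer}."
        q = (x @ p[pre + "Wq"] + p[pre + "bq"]).reshape(b, t, h, dh)
        k = (x @ p[pre + "Wk"] + p[pre + "bk"]).reshape(b, t, h, dh)
        v = (x @ p[pre + "Wv"] + p[pre + "bv"]).reshape(b, t, h, dh)
        q, k, v = (z.transpose(0, 2, 1, 3) for z in (q, k, v))
        scores = q @ k.transpose(0, 1, 3, 2) / np.sqrt(dh)
        probs = np.exp(scores - scores.max(-1, keepdims=True))
        probs /= probs.sum(-1, keepdims=True)
        ctx = (probs @ v).transpose(0, 2, 1, 3).reshape(b, t, h * dh)
        x = _layer_norm_np(x + ctx @ p[pre + "Wo"] + p[pre + "bo"],
                           p[pre + "ln1.g"], p[pre + "ln1.b"])
        hidden = x @ p[pre + "W1"] + p[pre + "b1"]
        hidden = hidden * 0.5 * (1 + erf(hidden / np.sqrt(2)))
        x = _layer_norm_np(x + hidden @ p[pre + "W2"] + p[pre + "b2"],
                           p[pre + "ln2.g"], p[pre + "ln2.b"])
    return x[:, 0, :] @ p["head.W"] + p["head.b"]


class TestPositionalEncoding:
    def test_position_zero_alternates_zero_one(self):
        pe = positional_encoding(4, 8)
        assert np.allclose(pe[0, 0::2], 0.0)
        assert np.allclose(pe[0, 1::2], 1.0)

    def test_values_bounded_by_one(self):
        pe = positional_encoding(512, 64)
        assert np.abs(pe).max() <= 1.0

    def test_closed_form_entry(self):
        pe = positional_encoding(2, 4)
        assert pe[1, 0] == pytest.approx(np.sin(1.0), abs=1e-12)
        assert pe[1, 2] == pytest.approx(np.sin(1.0 / 10000 ** 0.5), abs=1e-12)

    def test_odd_dim_rejected(self):
        with pytest.raises(ModelConfigError):
            positional_encoding(4, 7)


class TestSoftmax:
    def test_symmetry_and_normalization(self):
        assert np.allclose(softmax([0.0, 0.0]), [0.5, 0.5])
        assert softmax(np.random.default_rng(0).normal(size=16)).sum() == \
            pytest.approx(1.0, abs=1e-12)

    def test_known_ratio(self):
        assert np.allclose(softmax([np.log(2), 0.0]), [2 / 3, 1 / 3])

    def test_overflow_guarded(self):
        p = softmax([1e4, 0.0])
        assert np.isfinite(p).all() and p[0] == pytest.approx(1.0)


class TestForward:
    def test_logits_shape_and_probability_contract(self):
        model = SparseAttentionEncoder(small_config())
        vocab = build_vocabulary(3)
        (chunk,) = tokenize("ACGTACGTACGTN", vocab, max_embeddings=64)
        out = model.predict_chunk(chunk)
        assert out.logits.shape == (4,)
        assert out.probabilities.sum() == pytest.approx(1.0, abs=1e-6)
        assert (out.probabilities >= 0).all()

    def test_zero_head_gives_uniform_probabilities(self):
        model = SparseAttentionEncoder(small_config())
        model.params["head.W"].data[:] = 0
        model.params["head.b"].data[:] = 0
        vocab = build_vocabulary(3)
        (chunk,) = tokenize("ACGTACGTACGT", vocab, max_embeddings=64)
        out = model.predict_chunk(chunk)
        assert np.allclose(out.probabilities, 0.25, atol=1e-7)

    def test_dense_oracle_equivalence_many_random_instances(self):
        # window 16 covers all pairs for inputs of <= 9 tokens
        rng = np.random.default_rng(31)
        for trial in range(20):
            model = SparseAttentionEncoder(small_config(seed=trial))
            t = int(rng.integers(3, 9))
            ids = rng.integers(0, 125, size=(2, t))
            valid = np.ones((2, t), dtype=bool)
            logits, _ = model.forward(ids, valid)
            expected = dense_forward_oracle(model, ids)
            np.testing.assert_allclose(logits.data, expected,
                                       rtol=1e-4, atol=1e-4)

    def test_local_mask_zeroes_attention_outside_window(self):
        cfg = small_config(local_attention_window=4, global_att_tokens=(),
                           max_embeddings=64)
        model = SparseAttentionEncoder(cfg)
        t = 20
        ids = np.random.default_rng(5).integers(0, 125, size=(1, t))
        valid = np.ones((1, t), dtype=bool)
        _, attns = model.forward(ids, valid, collect_attention=True)
        idx = np.arange(t)
        outside = np.abs(idx[:, None] - idx[None, :]) > 2  # w/2 = 2
        for att in attns:
            assert np.all(att[0, :, outside] == 0.0)

    def test_global_positions_attend_everywhere(self):
        cfg = small_config(local_attention_window=4, global_att_tokens=(0, 7))
        model = SparseAttentionEncoder(cfg)
        t = 16
        ids = np.random.default_rng(6).integers(0, 125, size=(1, t))
        _, attns = model.forward(ids, np.ones((1, t), dtype=bool),
                                 collect_attention=True)
        for att in attns:
            assert (att[0, :, 0, :] > 0).all()   # row 0 attends to all
            assert (att[0, :, :, 7] > 0).all()   # everyone attends to col 7

    def test_permuting_tokens_changes_output(self):
        model = SparseAttentionEncoder(small_config())
        rng = np.random.default_rng(8)
        ids = rng.integers(1, 125, size=(1, 12))
        perm = ids[:, ::-1].copy()
        valid = np.ones((1, 12), dtype=bool)
        a, _ = model.forward(ids, valid)
        b, _ = model.forward(perm, valid)
        assert not np.allclose(a.data, b.data)

    def test_seeded_initialization_and_forward_deterministic(self):
        m1 = SparseAttentionEncoder(small_config(seed=42))
        m2 = SparseAttentionEncoder(small_config(seed=42))
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k].data,
                                          m2.params[k].data)
        ids = np.random.default_rng(0).integers(0, 125, size=(2, 10))
        valid = np.ones((2, 10), dtype=bool)
        a, _ = m1.forward(ids, valid)
        b, _ = m2.forward(ids, valid)
        np.testing.assert_array_equal(a.data, b.data)

    def test_padding_does_not_leak_into_valid_outputs(self):
        model = SparseAttentionEncoder(small_config())
        ids = np.random.default_rng(2).integers(0, 125, size=(1, 8))
        valid = np.ones((1, 8), dtype=bool)
        a, _ = model.forward(ids, valid)
        padded = np.concatenate([ids, np.full((1, 4), 125)], axis=1)
        valid_p = np.concatenate([valid, np.zeros((1, 4), bool)], axis=1)
        b, _ = model.forward(padded, valid_p)
        np.testing.assert_allclose(a.data, b.data, rtol=1e-4, atol=1e-5)


class TestGradients:
    def test_backward_matches_finite_differences(self):
        model = SparseAttentionEncoder(small_config())
        for p in model.params.values():
            p.data = p.data.astype(np.float64)
        ids = np.random.default_rng(1).integers(0, 125, size=(2, 7))
        valid = np.ones((2, 7), dtype=bool)
        labels = np.array([0, 3])
        weights = np.array([1.0, 0.5, 2.0, 1.5])

        def loss_fn():
            model.zero_grad()
            logits, _ = model.forward(ids, valid)
            return ag.weighted_cross_entropy_logits(logits, labels, weights)

        loss = loss_fn()
        loss.backward()
        grads = {k: p.grad.copy() for k, p in model.params.items()}
        rng = np.random.default_rng(2)
        checked = ["tok_emb", "layer0.Wq", "layer0.Wv", "layer1.W2",
                   "head.W", "layer0.ln1.g", "layer1.b1"]
        for name in checked:
            p = model.params[name]
            for _ in range(3):
                idx = tuple(rng.integers(0, s) for s in p.shape)
                eps = 1e-6
                orig = p.data[idx]
                p.data[idx] = orig + eps
                lp = float(loss_fn().data)
                p.data[idx] = orig - eps
                lm = float(loss_fn().data)
                p.data[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                assert grads[name][idx] == pytest.approx(
                    numeric, rel=5e-3, abs=1e-7), name


class TestAttentionRollback:
    def test_uniform_token_attention_stays_uniform(self):
        vocab = build_vocabulary(5)
        (chunk,) = tokenize("ACGTACGTACGTACGTACGT", vocab)
        out = attention_rollback(np.full(len(chunk.starts), 0.5), chunk)
        assert np.allclose(out, out[0])
        assert out.sum() == pytest.approx(0.5 * len(chunk.starts), abs=1e-9)

    def test_single_token_spreads_one_shared_value(self):
        vocab = build_vocabulary(5)
        (chunk,) = tokenize("ACGTA", vocab)
        out = attention_rollback(np.array([0.8]), chunk)
        assert len(out) == 5
        assert np.allclose(out, out[0])
        assert out.sum() == pytest.approx(0.8, abs=1e-9)

    def test_two_tokens_interpolate_linearly_between_midpoints(self):
        vocab = build_vocabulary(5)
        (chunk,) = tokenize("ACGTACG", vocab)  # starts 0 and 2, k=5, step=2
        out = attention_rollback(np.array([0.0, 1.0]), chunk,
                                 renormalize=False)
        # midpoints at 2 and 4; positions between take linearly spaced values
        assert out[2] == pytest.approx(0.0)
        assert out[3] == pytest.approx(0.5)
        assert out[4] == pytest.approx(1.0)
        assert len(out) == 7

    def test_mass_preserved_after_renormalization(self, rng):
        vocab = build_vocabulary(5)
        (chunk,) = tokenize("".join(rng.choice(list("ACGT"), 200)), vocab)
        vals = rng.random(len(chunk.starts))
        out = attention_rollback(vals, chunk)
        assert out.sum() == pytest.approx(vals.sum(), abs=1e-6)


class TestCheckpoint:
    def test_roundtrip_bitwise_weights_and_config(self, tmp_path):
        model = SparseAttentionEncoder(small_config(seed=17))
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, model, extra_meta={"epoch": 3})
        loaded, extra, meta = load_checkpoint(path)
        assert loaded.config == model.config
        assert meta["epoch"] == 3
        for k in model.params:
            np.testing.assert_array_equal(loaded.params[k].data,
                                          model.params[k].data)
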