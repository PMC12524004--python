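"""Decoder forward/backward correctness: oracle equivalence, causality,
loss analytics, gradient checks and training behavior."""

import math

import numpy as np
import pytest

from plm2mol.codec import build_default_vocabulary, encode_smiles
from plm2mol.decoder import (
    DecoderConfig,
    ProteinRecord,
    decoder_forward,
    embed_inputs,
    init_parameters,
    loss_and_grads,
    nll_loss,
    protein_cross_attention,
    sinusoidal_positions,
    train,
)

# ---------------------------------------------------------------------------
# independent dense oracle: explicit per-head, per-position loops
# ---------------------------------------------------------------------------


def oracle_softmax(v):
    e = [math.exp(x - max(v)) for x in v]
    s = sum(e)
    return [x / s for x in e]


def oracle_layernorm(row, g, b, eps=1e-5):
    mu = sum(row) / len(row)
    var = sum((x - mu) ** 2 for x in row) / len(row)
    return [g[i] * (row[i] - mu) / math.sqrt(var + eps) + b[i]
            for i in range(len(row))]


def oracle_forward(params, indices, x):
    """Plain-python re-derivation of the decoder forward pass."""
    cfg = params.config
    w = params.weights
    L = len(indices)
    h, dk, d = cfg.n_heads, cfg.d_k, cfg.d_model
    Y = (w["E"][indices] + params.positional[:L]).tolist()

    def matvecs(M, W):  # rows of M times W, as lists
        return (np.array(M) @ np.array(W)).tolist()

    for layer in range(cfg.n_layers):
        p = f"layer{layer}."
        # self-attention, one head and one query position at a time
        Q = matvecs(Y, w[p + "self.Wq"])
        K = matvecs(Y, w[p + "self.Wk"])
        V = matvecs(Y, w[p + "self.Wv"])
        heads = [[None] * L for _ in range(h)]
        for i in range(h):
            sl = slice(i * dk, (i + 1) * dk)
            for t in range(L):
                scores = [
                    sum(Q[t][sl][m] * K[u][sl][m] for m in range(dk)) / math.sqrt(dk)
                    for u in range(t + 1)  # causal: keys up to position t
                ]
                att = oracle_softmax(scores)
                heads[i][t] = [
                    sum(att[u] * V[u][sl][m] for u in range(t + 1))
                    for m in range(dk)
                ]
        concat = [[v for i in range(h) for v in heads[i][t]] for t in range(L)]
        sa = matvecs(concat, w[p + "self.Wo"])
        Y = [
            oracle_layernorm(
                [Y[t][j] + sa[t][j] for j in range(d)],
                w[p + "ln1.g"], w[p + "ln1.b"],
            )
            for t in range(L)
        ]
        # cross-attention: single key/value row per head
        Q = matvecs(Y, w[p + "cross.Wq"])
        K1 = (np.array(x) @ np.array(w[p + "cross.Wk"])).tolist()
        V1 = (np.array(x) @ np.array(w[p + "cross.Wv"])).tolist()
        heads = [[None] * L for _ in range(h)]
        for i in range(h):
            sl = slice(i * dk, (i + 1) * dk)
            for t in range(L):
                # a single key: softmax of a length-1 score list is [1.0]
                att = oracle_softmax(
                    [sum(Q[t][sl][m] * K1[sl][m] for m in range(dk))
                     / math.sqrt(dk)]
                )
                heads[i][t] = [att[0] * V1[sl][m] for m in range(dk)]
        concat = [[v for i in range(h) for v in heads[i][t]] for t in range(L)]
        ca = matvecs(concat, w[p + "cross.Wo"])
        Y = [
            oracle_layernorm(
                [Y[t][j] + ca[t][j] for j in range(d)],
                w[p + "ln2.g"], w[p + "ln2.b"],
            )
            for t in range(L)
        ]
        # feed-forward
        H = [
            [max(0.0, v + w[p + "ffn.b1"][j])
             for j, v in enumerate(row)]
            for row in matvecs(Y, w[p + "ffn.W1"])
        ]
        ff = [
            [v + w[p + "ffn.b2"][j] for j, v in enumerate(row)]
            for row in matvecs(H, w[p + "ffn.W2"])
        ]
        Y = [
            oracle_layernorm(
                [Y[t][j] + ff[t][j] for j in range(d)],
                w[p + "ln3.g"], w[p + "ln3.b"],
            )
            for t in range(L)
        ]
    logits = np.array(Y) @ w["Wout"] + w["bout"]
    return logits


# ---------------------------------------------------------------------------


class TestEmbedInputs:
    def test_zero_embedding_gives_positional(self, tiny_params, tiny_config):
        params = tiny_params.copy()
        params.weights["E"][:] = 0.0
        S = np.eye(tiny_config.vocab_size)[:Nseq(tiny_config)]
        Y = embed_inputs(S, params)
        assert np.allclose(Y, params.positional[: S.shape[0]])

    def test_zero_positional_selects_embedding_rows(self, tiny_params):
        params = tiny_params.copy()
        params.positional[:] = 0.0
        S = np.zeros((3, params.config.vocab_size))
        S[0, 2] = S[1, 5] = S[2, 0] = 1.0
        Y = embed_inputs(S, params)
        assert np.allclose(Y, params.weights["E"][[2, 5, 0]])

    def test_matches_triple_loop(self, tiny_params):
        rng = np.random.default_rng(0)
        L, s, d = 3, tiny_params.config.vocab_size, tiny_params.config.d_model
        S = np.zeros((L, s))
        for t, j in enumerate(rng.integers(0, s, size=L)):
            S[t, j] = 1.0
        Y = embed_inputs(S, tiny_params)
        expected = np.zeros((L, d))
        for t in range(L):
            for j in range(d):
                expected[t, j] = (
                    sum(S[t, k] * tiny_params.weights["E"][k, j] for k in range(s))
                    + tiny_params.positional[t, j]
                )
        assert np.allclose(Y, expected)

    def test_shape_mismatch_error(self, tiny_params):
        with pytest.raises(ValueError):
            embed_inputs(np.zeros((3, 99)), tiny_params)


def Nseq(config):
    return min(4, config.seq_len)


class TestCrossAttention:
    def test_rows_identical_singleton_key(self, tiny_params):
        rng = np.random.default_rng(1)
        cfg = tiny_params.config
        Y = rng.normal(size=(cfg.seq_len, cfg.d_model))
        x = rng.normal(size=cfg.d_model)
        Z = protein_cross_attention(x, Y, tiny_params)
        assert np.allclose(Z, Z[0])

    def test_zero_value_projection(self, tiny_params):
        params = tiny_params.copy()
        cfg = params.config
        params.weights["layer0.cross.Wv"][:] = 0.0
        rng = np.random.default_rng(2)
        Z = protein_cross_attention(
            rng.normal(size=cfg.d_model),
            rng.normal(size=(3, cfg.d_model)),
            params,
        )
        assert np.allclose(Z, 0.0)

    def test_matches_dense_formula(self, tiny_params):
        """Direct evaluation of Z = softmax(Q K^T / sqrt(dk)) V per head."""
        rng = np.random.default_rng(3)
        cfg = tiny_params.config
        w = tiny_params.weights
        Y = rng.normal(size=(3, cfg.d_model))
        x = rng.normal(size=cfg.d_model)
        Z, trace = protein_cross_attention(x, Y, tiny_params, return_trace=True)
        h, dk = cfg.n_heads, cfg.d_k
        heads = []
        for i in range(h):
            sl = slice(i * dk, (i + 1) * dk)
            Qi = Y @ w["layer0.cross.Wq"][:, sl]
            Ki = (x @ w["layer0.cross.Wk"])[sl][None]
            Vi = (x @ w["layer0.cross.Wv"])[sl][None]
            scores = Qi @ Ki.T / math.sqrt(dk)
            att = np.exp(scores - scores.max(axis=1, keepdims=True))
            att /= att.sum(axis=1, keepdims=True)
            heads.append(att @ Vi)
        expected = np.concatenate(heads, axis=1) @ w["layer0.cross.Wo"]
        assert np.allclose(Z, expected, atol=1e-10)
        assert trace.K.shape == (h, 1, dk)
        assert trace.V.shape == (h, 1, dk)

    def test_nonfinite_embedding_error(self, tiny_params):
        cfg = tiny_params.config
        x = np.zeros(cfg.d_model)
        x[0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            protein_cross_attention(x, np.zeros((2, cfg.d_model)), tiny_params)


class TestDecoderForward:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        cfg = DecoderConfig(
            n_layers=2, n_heads=2, d_model=8, seq_len=6, vocab_size=7,
            ffn_dim=16, dropout=0.0,
        )
        params = init_parameters(cfg, seed=seed)
        rng = np.random.default_rng(seed + 100)
        indices = rng.integers(0, cfg.vocab_size, size=cfg.seq_len)
        x = rng.normal(size=cfg.d_model)
        logits = decoder_forward(x, indices, params)
        expected = oracle_forward(params, indices, x)
        assert logits.shape == (cfg.seq_len, cfg.vocab_size)
        assert np.max(np.abs(logits - expected)) < 1e-5

    def test_causality_all_positions(self, tiny_params):
        cfg = tiny_params.config
        rng = np.random.default_rng(8)
        indices = rng.integers(0, cfg.vocab_size, size=cfg.seq_len)
        x = rng.normal(size=cfg.d_model)
        base = decoder_forward(x, indices, tiny_params)
        for j in range(cfg.seq_len):
            perturbed = indices.copy()
            perturbed[j] = (perturbed[j] + 1) % cfg.vocab_size
            out = decoder_forward(x, perturbed, tiny_params)
            assert np.allclose(out[:j], base[:j]), f"position {j} leaks backwards"

    def test_zero_output_projection_uniform_softmax(self, tiny_params):
        params = tiny_params.copy()
        params.weights["Wout"][:] = 0.0
        params.weights["bout"][:] = 0.0
        cfg = params.config
        logits = decoder_forward(
            np.zeros(cfg.d_model), np.zeros(cfg.seq_len, dtype=int), params
        )
        probs = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        assert np.allclose(probs, 1.0 / cfg.vocab_size)

    def test_onehot_and_index_inputs_agree(self, tiny_params):
        cfg = tiny_params.config
        rng = np.random.default_rng(9)
        indices = rng.integers(0, cfg.vocab_size, size=cfg.seq_len)
        onehot = np.eye(cfg.vocab_size)[indices]
        x = rng.normal(size=cfg.d_model)
        assert np.allclose(
            decoder_forward(x, indices, tiny_params),
            decoder_forward(x, onehot, tiny_params),
        )


class TestLoss:
    def test_perfect_prediction_zero_loss(self):
        targets = np.array([[1, 2, 3]])
        logits = np.full((1, 3, 5), -1e3)
        for t, c in enumerate(targets[0]):
            logits[0, t, c] = 1e3
        mask = np.ones((1, 3))
        assert nll_loss(logits, targets, mask) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_prediction_log_vocab(self):
        s = 33
        logits = np.zeros((2, 4, s))
        targets = np.zeros((2, 4), dtype=int)
        mask = np.ones((2, 4))
        assert nll_loss(logits, targets, mask) == pytest.approx(math.log(33))

    def test_pad_masking_invariance(self):
        rng = np.random.default_rng(4)
        logits = rng.normal(size=(1, 5, 7))
        targets = rng.integers(0, 7, size=(1, 5))
        mask = np.array([[1, 1, 1, 0, 0]], dtype=float)
        base = nll_loss(logits, targets, mask)
        # appending more masked positions leaves the loss unchanged
        logits2 = np.concatenate([logits, rng.normal(size=(1, 3, 7))], axis=1)
        targets2 = np.concatenate([targets, rng.integers(0, 7, size=(1, 3))], axis=1)
        mask2 = np.concatenate([mask, np.zeros((1, 3))], axis=1)
        assert nll_loss(logits2, targets2, mask2) == pytest.approx(base)

    def test_all_masked_error(self):
        with pytest.raises(ValueError, match="masked"):
            nll_loss(np.zeros((1, 2, 3)), np.zeros((1, 2), dtype=int),
                     np.zeros((1, 2)))


class TestGradients:
    def test_finite_difference_check(self, tiny_config):
        params = init_parameters(tiny_config, seed=1)
        rng = np.random.default_rng(0)
        idx = rng.integers(0, tiny_config.vocab_size, size=(3, tiny_config.seq_len))
        idx[:, 0] = 0
        pad_id = tiny_config.vocab_size - 1
        idx[0, -1] = pad_id
        x = rng.normal(size=(3, tiny_config.d_model))
        _, grads = loss_and_grads(params, idx, x, pad_id)
        eps = 1e-6
        for name in ("layer0.self.Wq", "layer1.cross.Wv", "layer0.ffn.W1",
                     "layer1.ln3.g", "E", "Wout"):
            flat = params.weights[name].reshape(-1)
            g = grads[name].reshape(-1)
            for k in rng.choice(flat.size, size=4, replace=False):
                orig = flat[k]
                flat[k] = orig + eps
                lp, _ = loss_and_grads(params, idx, x, pad_id)
                flat[k] = orig - eps
                lm, _ = loss_and_grads(params, idx, x, pad_id)
                flat[k] = orig
                num = (lp - lm) / (2 * eps)
                assert abs(num - g[k]) < 1e-4 * max(1.0, abs(num)), name


class TestTraining:
    @staticmethod
    def one_pair_dataset(n_copies=50):
        vocab = build_default_vocabulary()
        enc = encode_smiles("CCOC(=O)NC", max_raw_len=14, vocab=vocab)
        x = np.random.default_rng(0).normal(size=16)
        return [(x, enc)] * n_copies, vocab

    @staticmethod
    def small_config(epochs):
        return DecoderConfig(
            n_layers=1, n_heads=2, d_model=16, seq_len=16, vocab_size=33,
            ffn_dim=32, dropout=0.0, epochs=epochs, batch_size=10,
            learning_rate=0.01,
        )

    def test_overfits_single_repeated_pair(self):
        dataset, vocab = self.one_pair_dataset()
        config = self.small_config(epochs=40)  # 40 epochs x 5 batches = 200 steps
        _, history = train(dataset, config, seed=0, pad_id=vocab.pad_id)
        assert history[-1] < 0.1 * history[0]

    def test_seeded_reproducibility(self):
        dataset, vocab = self.one_pair_dataset(20)
        config = self.small_config(epochs=3)
        _, h1 = train(dataset, config, seed=3, pad_id=vocab.pad_id)
        _, h2 = train(dataset, config, seed=3, pad_id=vocab.pad_id)
        assert h1 == h2

    def test_loss_trend_decreasing(self):
        dataset, vocab = self.one_pair_dataset(30)
        config = self.small_config(epochs=15)
        _, history = train(dataset, config, seed=1, pad_id=vocab.pad_id)
        window = [np.mean(history[i : i + 5]) for i in range(0, 15, 5)]
        assert window[0] > window[1] > window[2]

    def test_empty_dataset_error(self):
        with pytest.raises(ValueError, match="empty"):
            train([], self.small_config(1))
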