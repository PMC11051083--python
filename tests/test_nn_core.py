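"""Oracle and property tests for the transformer building blocks."""

import numpy as np
import pytest

from tricoat import nn
from tricoat.nn.layers import CoAttention, EncoderLayer, MultiheadSelfAttention

from reference import (attention_loops, coattention_loops,
                       encoder_layer_loops, multihead_self_attention_loops)


def _grad_check(loss_fn, tensors, eps=1e-6, tol=1e-6):
    loss = loss_fn()
    loss.backward()
    grads = [t.grad.copy() for t in tensors]
    for t, g in zip(tensors, grads):
        num = np.zeros_like(t.data)
        it = np.nditer(t.data, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            t.data[i] += eps
            fp = float(loss_fn().data)
            t.data[i] -= 2 * eps
            fm = float(loss_fn().data)
            t.data[i] += eps
            num[i] = (fp - fm) / (2 * eps)
        assert np.abs(num - g).max() < tol


class TestAutodiff:
    def test_attention_graph_gradients_match_finite_differences(self, rng):
        q = nn.Tensor(rng.normal(size=(2, 3, 4)), requires_grad=True)
        k = nn.Tensor(rng.normal(size=(2, 5, 4)), requires_grad=True)
        v = nn.Tensor(rng.normal(size=(2, 5, 4)), requires_grad=True)

        def loss():
            out = ((q @ k.swapaxes(-1, -2)) * 0.5).softmax(-1) @ v
            return (out * out).sum()

        _grad_check(loss, [q, k, v])

    def test_layernorm_gelu_chain_gradients(self, rng):
        x = nn.Tensor(rng.normal(size=(4, 6)), requires_grad=True)
        g = nn.Parameter(rng.normal(size=6))
        b = nn.Parameter(rng.normal(size=6))

        def loss():
            return (nn.layer_norm(x, g, b).gelu() ** 2.0).sum()

        _grad_check(loss, [x, g, b])

    def test_embedding_gradient_accumulates_repeated_indices(self, rng):
        W = nn.Parameter(rng.normal(size=(5, 3)))
        idx = np.array([1, 1, 4])
        (W[idx] * W[idx]).sum().backward()
        expected = np.zeros((5, 3))
        np.add.at(expected, idx, 2 * W.data[idx])
        assert np.allclose(W.grad, expected)

    def test_broadcast_backward_unbroadcasts(self, rng):
        a = nn.Tensor(rng.normal(size=(3, 1, 4)), requires_grad=True)
        b = nn.Tensor(rng.normal(size=(2, 4)), requires_grad=True)

        def loss():
            return ((a * b) ** 2.0).sum()

        _grad_check(loss, [a, b])


class TestMultiheadAttention:
    @pytest.mark.parametrize("n_tokens,k,n_heads", [(5, 8, 2), (7, 16, 4), (3, 8, 1)])
    def test_matches_loop_oracle(self, rng, n_tokens, k, n_heads):
        """Vectorized MHA equals a per-row, per-head loop implementation."""
        mha = MultiheadSelfAttention(k, n_heads, rng)
        x = rng.normal(size=(2, n_tokens, k))
        out = mha(nn.Tensor(x)).data
        for s in range(2):
            ref = multihead_self_attention_loops(
                x[s], mha.w_q.weight.data, mha.w_q.bias.data,
                mha.w_k.weight.data, mha.w_k.bias.data, mha.w_v.weight.data,
                mha.w_v.bias.data, mha.w_o.weight.data, mha.w_o.bias.data,
                n_heads)
            assert np.abs(out[s] - ref).max() < 1e-5

    def test_attention_rows_sum_to_one(self, rng):
        mha = MultiheadSelfAttention(8, 2, rng)
        mha(nn.Tensor(rng.normal(size=(3, 6, 8))))
        assert np.abs(mha.last_weights.sum(axis=-1) - 1.0).max() < 1e-6


class TestEncoderLayer:
    @pytest.mark.parametrize("n_tokens,k,n_heads", [(5, 8, 2), (8, 16, 4)])
    def test_matches_pre_ln_loop_oracle(self, rng, n_tokens, k, n_heads):
        """One encoder layer equals the loop-based pre-LN MHA+FF reference."""
        layer = EncoderLayer(k, n_heads, dropout=0.0, rng=rng)
        layer.eval()
        x = rng.normal(size=(1, n_tokens, k))
        out = layer(nn.Tensor(x)).data[0]
        ref = encoder_layer_loops(x[0], layer)
        assert np.abs(out - ref).max() < 1e-5

    def test_token_permutation_equivariance(self, rng):
        """Without positional encoding, permuting tokens permutes outputs."""
        layer = EncoderLayer(8, 2, dropout=0.0, rng=rng)
        layer.eval()
        x = rng.normal(size=(1, 6, 8))
        perm = rng.permutation(6)
        out = layer(nn.Tensor(x)).data
        out_perm = layer(nn.Tensor(x[:, perm])).data
        assert np.allclose(out[:, perm], out_perm, atol=1e-10)


class TestCoAttention:
    @pytest.mark.parametrize("project", [True, False])
    def test_matches_loop_oracle(self, rng, project):
        co = CoAttention(8, rng, project=project)
        q = rng.normal(size=(1, 4, 8))
        kv = rng.normal(size=(1, 3, 8))
        out, w = co(nn.Tensor(q), nn.Tensor(kv))
        ref_out, ref_w = coattention_loops(q[0], kv[0], co)
        assert np.abs(out.data[0] - ref_out).max() < 1e-5
        assert np.abs(w.data[0] - ref_w).max() < 1e-5

    def test_single_clinical_token_gives_unit_weights(self, rng):
        """Softmax over a singleton: all weights exactly 1 and all output
        rows equal the single projected value vector."""
        co = CoAttention(8, rng)
        q = rng.normal(size=(1, 5, 8))
        kv = rng.normal(size=(1, 1, 8))
        out, w = co(nn.Tensor(q), nn.Tensor(kv))
        assert np.allclose(w.data, 1.0)
        v = kv[0] @ co.w_v.weight.data + co.w_v.bias.data
        assert np.allclose(out.data[0], np.repeat(v, 5, axis=0), atol=1e-12)

    def test_identical_logits_give_uniform_weights(self, rng):
        """Identical clinical tokens -> uniform weights, mean-of-values output."""
        co = CoAttention(8, rng)
        q = rng.normal(size=(1, 4, 8))
        kv = np.repeat(rng.normal(size=(1, 1, 8)), 3, axis=1)
        out, w = co(nn.Tensor(q), nn.Tensor(kv))
        assert np.allclose(w.data, 1.0 / 3.0, atol=1e-12)

    def test_weights_permute_with_clinical_token_order(self, rng):
        co = CoAttention(8, rng)
        q = rng.normal(size=(1, 4, 8))
        kv = rng.normal(size=(1, 5, 8))
        perm = rng.permutation(5)
        _, w = co(nn.Tensor(q), nn.Tensor(kv))
        _, w_perm = co(nn.Tensor(q), nn.Tensor(kv[:, perm]))
        assert np.allclose(w.data[:, :, perm], w_perm.data, atol=1e-10)

    def test_zero_clinical_tokens_rejected(self, rng):
        co = CoAttention(8, rng)
        with pytest.raises(ValueError, match="at least one"):
            co(nn.Tensor(rng.normal(size=(1, 4, 8))),
               nn.Tensor(np.empty((1, 0, 8))))


class TestTraining:
    def test_adam_reduces_loss_on_toy_regression(self, rng):
        lin = nn.Linear(4, 1, rng)
        X = rng.normal(size=(64, 4))
        w_true = np.array([[1.0], [-2.0], [0.5], [3.0]])
        y = X @ w_true
        opt = nn.Adam(lin.parameters(), lr=0.05)
        losses = []
        for _ in range(200):
            pred = lin(nn.Tensor(X))
            loss = ((pred - nn.Tensor(y)) ** 2.0).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        assert losses[-1] < 0.01 * losses[0]

    def test_cross_entropy_matches_manual_log_loss(self, rng):
        logits = nn.Tensor(rng.normal(size=(6, 3)), requires_grad=True)
        y = np.array([0, 1, 2, 0, 1, 2])
        loss = nn.cross_entropy(logits, y)
        z = logits.data
        p = np.exp(z - z.max(-1, keepdims=True))
        p /= p.sum(-1, keepdims=True)
        manual = -np.mean(np.log(p[np.arange(6), y]))
        assert np.isclose(float(loss.data), manual)
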