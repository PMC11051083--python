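"""Independent loop-based reference implementations used as test oracles.

Everything here is written with explicit Python loops and plain numpy so it
shares no code path with the package's vectorized autodiff implementation.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.special import erf


def softmax_rows(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    for i in range(z.shape[0]):
        row = z[i] - z[i].max()
        e = np.exp(row)
        out[i] = e / e.sum()
    return out


def attention_loops(q: np.ndarray, k: np.ndarray, v: np.ndarray,
                    scale: float) -> tuple[np.ndarray, np.ndarray]:
    """Single-head scaled dot-product attention, one query row at a time."""
    tq, d = q.shape
    tk = k.shape[0]
    weights = np.zeros((tq, tk))
    for i in range(tq):
        logits = np.array([np.dot(q[i], k[j]) * scale for j in range(tk)])
        logits -= logits.max()
        e = np.exp(logits)
        weights[i] = e / e.sum()
    out = np.zeros((tq, v.shape[1]))
    for i in range(tq):
        for j in range(tk):
            out[i] += weights[i, j] * v[j]
    return out, weights


def multihead_self_attention_loops(x, w_q, b_q, w_k, b_k, w_v, b_v, w_o, b_o,
                                   n_heads: int) -> np.ndarray:
    """Multihead self-attention for a single (tokens, k) sequence."""
    t, k = x.shape
    d = k // n_heads
    q = x @ w_q + b_q
    kk = x @ w_k + b_k
    v = x @ w_v + b_v
    heads = []
    for h in range(n_heads):
        sl = slice(h * d, (h + 1) * d)
        out_h, _ = attention_loops(q[:, sl], kk[:, sl], v[:, sl],
                                   1.0 / np.sqrt(d))
        heads.append(out_h)
    return np.concatenate(heads, axis=1) @ w_o + b_o


def layer_norm_loops(x, gamma, beta, eps=1e-5):
    out = np.empty_like(x, dtype=float)
    for i in range(x.shape[0]):
        mu = x[i].mean()
        var = ((x[i] - mu) ** 2).mean()
        out[i] = (x[i] - mu) / np.sqrt(var + eps) * gamma + beta
    return out


def gelu_ref(x):
    return x * 0.5 * (1.0 + erf(x / np.sqrt(2.0)))


def encoder_layer_loops(x, layer) -> np.ndarray:
    """Pre-LN transformer layer (one sequence) mirroring the published
    formulation: x + MHA(LN(x)); then + FF(LN(.))."""
    mha = layer.mha
    h = layer_norm_loops(x, layer.ln1.gamma.data, layer.ln1.beta.data)
    attn_out = multihead_self_attention_loops(
        h, mha.w_q.weight.data, mha.w_q.bias.data, mha.w_k.weight.data,
        mha.w_k.bias.data, mha.w_v.weight.data, mha.w_v.bias.data,
        mha.w_o.weight.data, mha.w_o.bias.data, mha.n_heads)
    x1 = attn_out + x
    h2 = layer_norm_loops(x1, layer.ln2.gamma.data, layer.ln2.beta.data)
    ff = gelu_ref(h2 @ layer.ff.fc1.weight.data + layer.ff.fc1.bias.data)
    ff = ff @ layer.ff.fc2.weight.data + layer.ff.fc2.bias.data
    return ff + x1


def coattention_loops(queries, keyvalues, co) -> tuple[np.ndarray, np.ndarray]:
    """Single-head cross-attention with the block's learned projections."""
    q = queries @ co.w_q.weight.data + co.w_q.bias.data if co.project else queries
    k = keyvalues @ co.w_k.weight.data + co.w_k.bias.data if co.project else keyvalues
    v = keyvalues @ co.w_v.weight.data + co.w_v.bias.data if co.project else keyvalues
    return attention_loops(q, k, v, 1.0 / np.sqrt(co.k))


def ovo_auroc_concordance(y_true, proba, classes) -> float:
    """One-vs-one AUROC by exhaustive concordant/discordant/tied counting."""
    y_true = np.asarray(y_true)
    pair_scores = []
    for (ia, a), (ib, b) in itertools.combinations(enumerate(classes), 2):
        idx_a = np.flatnonzero(y_true == a)
        idx_b = np.flatnonzero(y_true == b)
        both = []
        for col, pos, neg in ((ia, idx_a, idx_b), (ib, idx_b, idx_a)):
            conc = ties = 0
            for i in pos:
                for j in neg:
                    if proba[i, col] > proba[j, col]:
                        conc += 1
                    elif proba[i, col] == proba[j, col]:
                        ties += 1
            both.append((conc + 0.5 * ties) / (len(pos) * len(neg)))
        pair_scores.append(0.5 * (both[0] + both[1]))
    return float(np.mean(pair_scores))
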