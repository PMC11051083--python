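"""Neural-network building blocks: linear maps, layer norm, multihead
self-attention, pre-LN transformer encoder layers and single-head
cross-modal (co-)attention."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, cat, layer_norm


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class with recursive parameter discovery and train/eval mode."""

    training: bool = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        self._collect(params, seen)
        return params

    def _collect(self, params, seen):
        for value in vars(self).values():
            self._collect_value(value, params, seen)

    @staticmethod
    def _collect_value(value, params, seen):
        if isinstance(value, Parameter):
            if id(value) not in seen:
                seen.add(id(value))
                params.append(value)
        elif isinstance(value, Module):
            value._collect(params, seen)
        elif isinstance(value, (list, tuple)):
            for v in value:
                Module._collect_value(v, params, seen)

    def modules(self):
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for v in value:
                    if isinstance(v, Module):
                        yield from v.modules()

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state does not match parameter count")
        for p, s in zip(params, state):
            p.data = s.copy()


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(d_in)
        self.weight = Parameter(rng.uniform(-bound, bound, size=(d_in, d_out)))
        self.bias = Parameter(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Embedding(Module):
    """Lookup table mapping integer indices to learned vectors."""

    def __init__(self, n: int, dim: int, rng: np.random.Generator):
        self.weight = Parameter(rng.normal(0.0, 1.0, size=(n, dim)))

    def __call__(self, idx: np.ndarray) -> Tensor:
        return self.weight[np.asarray(idx, dtype=np.intp)]


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta, self.eps)


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        self.p = float(p)
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(keep)


class MultiheadSelfAttention(Module):
    """Scaled dot-product self-attention with ``n_heads`` parallel heads.

    Exposes ``last_weights`` (batch, heads, tokens, tokens) from the most
    recent forward pass for inspection and tests.
    """

    def __init__(self, k: int, n_heads: int, rng: np.random.Generator):
        if k % n_heads != 0:
            raise ValueError(f"n_heads={n_heads} must divide k={k}")
        self.k, self.n_heads, self.d_head = k, n_heads, k // n_heads
        self.w_q = Linear(k, k, rng)
        self.w_k = Linear(k, k, rng)
        self.w_v = Linear(k, k, rng)
        self.w_o = Linear(k, k, rng)
        self.last_weights: np.ndarray | None = None

    def _split(self, x: Tensor, b: int, t: int) -> Tensor:
        return x.reshape(b, t, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def __call__(self, x: Tensor) -> Tensor:
        b, t, _ = x.shape
        # scale folded into Q so no (b, h, t, t) temporary beyond the logits
        q = self._split(self.w_q(x), b, t) * (1.0 / np.sqrt(self.d_head))
        k = self._split(self.w_k(x), b, t)
        v = self._split(self.w_v(x), b, t)
        attn = (q @ k.swapaxes(-1, -2)).softmax(axis=-1)
        self.last_weights = attn.data
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(b, t, self.k)
        return self.w_o(out)


class FeedForward(Module):
    """Position-wise MLP with GELU, hidden width ``mult``·k."""

    def __init__(self, k: int, rng: np.random.Generator, mult: int = 4):
        self.fc1 = Linear(k, mult * k, rng)
        self.fc2 = Linear(mult * k, k, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class EncoderLayer(Module):
    """Pre-LN transformer layer: x + MHA(LN(x)), then x + FF(LN(x))."""

    def __init__(self, k: int, n_heads: int, dropout: float, rng: np.random.Generator):
        self.ln1 = LayerNorm(k)
        self.mha = MultiheadSelfAttention(k, n_heads, rng)
        self.ln2 = LayerNorm(k)
        self.ff = FeedForward(k, rng)
        self.drop1 = Dropout(dropout, rng)
        self.drop2 = Dropout(dropout, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.drop1(self.mha(self.ln1(x))) + x
        return self.drop2(self.ff(self.ln2(x))) + x


class Encoder(Module):
    def __init__(self, k: int, n_layers: int, n_heads: int, dropout: float,
                 rng: np.random.Generator):
        self.layers = [EncoderLayer(k, n_heads, dropout, rng) for _ in range(n_layers)]

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class CoAttention(Module):
    """Single-head cross-modal attention.

    Queries come from one modality's encoded tokens, keys and values from
    another's; the output lives in query-token space and re-weights the
    key/value modality.  With ``project=False`` the encoded tokens are used
    directly as Q/K/V without learned projections.
    """

    def __init__(self, k: int, rng: np.random.Generator, project: bool = True):
        self.k = k
        self.project = project
        if project:
            self.w_q = Linear(k, k, rng)
            self.w_k = Linear(k, k, rng)
            self.w_v = Linear(k, k, rng)
        self.last_weights: np.ndarray | None = None

    def __call__(self, queries: Tensor, keyvalues: Tensor) -> tuple[Tensor, Tensor]:
        if keyvalues.shape[-2] == 0:
            raise ValueError("co-attention requires at least one key/value token")
        q = self.w_q(queries) if self.project else queries
        k = self.w_k(keyvalues) if self.project else keyvalues
        v = self.w_v(keyvalues) if self.project else keyvalues
        weights = ((q * (1.0 / np.sqrt(self.k))) @ k.swapaxes(-1, -2)).softmax(axis=-1)
        self.last_weights = weights.data
        return weights @ v, weights


__all__ = [
    "Parameter", "Module", "Linear", "Embedding", "LayerNorm", "Dropout",
    "MultiheadSelfAttention", "FeedForward", "EncoderLayer", "Encoder",
    "CoAttention", "cat",
]
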