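"""The tri-modal co-attention (Tri-COAT) classifier.

Architecture
------------
Each modality is tokenized — one token per ROI (4 morphometric traits,
shared affine map to k), per SNP (dosage + 3 GWAS attributes affinely mapped
to k/2, concatenated with a learned chromosome embedding of size k/2), and
per clinical score (independent per-feature 1->k affine maps).  A learnable
class token is prepended to each sequence and each modality runs through its
own pre-LN transformer encoder,

    F'_l = MHA(LN(F_{l-1})) + F_{l-1},
    F_l  = FF(LN(F'_l)) + F'_l.

The encoded genetics and imaging sequences then act as queries in two
single-head co-attention blocks whose keys and values come from the encoded
clinical sequence: softmax(Q K_C^T / sqrt(d_k)) V_C.  The co-attended class
tokens of both query modalities are concatenated (2k) and classified by an
MLP with one hidden layer.  No positional encodings: tokens are set-like.

:class:`TriCoatClassifier` wraps the network as a scikit-learn style
estimator over :class:`~tricoat.features.ModalityArrays`, with per-epoch
checkpoint selection on a validation set (highest one-vs-one AUROC).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .data import SUBTYPES
from .features import ModalityArrays
from .metrics import auroc_ovo

MODALITIES = ("imaging", "genetics", "clinical")
N_CHROMOSOMES = 24  # 1..22 autosomes, 23 = X-coded


@dataclass
class ModelConfig:
    """Hyperparameters of the Tri-COAT network.

    Defaults follow the published configuration: k=256 embedding, 4 encoder
    layers with 4 self-attention heads, single-head co-attention, a 256-unit
    MLP head, Adam at lr 1e-4, 100 epochs.  Feed-forward width (4k), GELU,
    dropout 0.1 and batch size 32 are package defaults.
    """

    k: int = 256
    n_layers: int = 4
    n_heads: int = 4
    mlp_hidden: int = 256
    n_classes: int = 3
    learning_rate: float = 1e-4
    epochs: int = 100
    batch_size: int = 32
    dropout: float = 0.1
    joint: str = "class_token"        # or "flatten"
    coattn_project: bool = True
    include_clinical_token: bool = False
    seed: int = 0

    def validate(self) -> "ModelConfig":
        if self.k % 2 != 0:
            raise ValueError(f"k must be even (genetic tokenizer uses k/2), got {self.k}")
        if self.k % self.n_heads != 0:
            raise ValueError(f"n_heads={self.n_heads} must divide k={self.k}")
        if self.joint not in ("class_token", "flatten"):
            raise ValueError(f"joint must be 'class_token' or 'flatten', got {self.joint!r}")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        return self


class TriCoatNetwork(nn.Module):
    """Tokenizers, per-modality encoders, co-attention and MLP head.

    With a single entry in ``modalities`` the network degrades to that
    modality's encoder plus class-token MLP head (the single-modality
    ablation backbone); with all three it is the full co-attention model.
    """

    def __init__(self, config: ModelConfig, n_roi: int, n_snp: int,
                 n_clinical: int, rng: np.random.Generator,
                 modalities: tuple[str, ...] = MODALITIES):
        config.validate()
        self.config = config
        self.modalities = tuple(modalities)
        unknown = set(self.modalities) - set(MODALITIES)
        if unknown:
            raise ValueError(f"unknown modalities {sorted(unknown)}")
        if len(self.modalities) not in (1, 3):
            raise ValueError("modalities must be a single modality or all three")
        k = config.k
        self.n_roi, self.n_snp, self.n_clinical = n_roi, n_snp, n_clinical

        if "imaging" in self.modalities:
            self.img_proj = nn.Linear(4, k, rng)
            self.cls_img = nn.Parameter(rng.normal(0.0, 0.02, size=(1, 1, k)))
            self.enc_img = nn.Encoder(k, config.n_layers, config.n_heads,
                                      config.dropout, rng)
        if "genetics" in self.modalities:
            self.snp_proj = nn.Linear(4, k // 2, rng)
            self.chrom_emb = nn.Embedding(N_CHROMOSOMES, k // 2, rng)
            self.cls_gen = nn.Parameter(rng.normal(0.0, 0.02, size=(1, 1, k)))
            self.enc_gen = nn.Encoder(k, config.n_layers, config.n_heads,
                                      config.dropout, rng)
        if "clinical" in self.modalities:
            bound = 1.0
            self.clin_w = nn.Parameter(rng.uniform(-bound, bound, size=(n_clinical, k)))
            self.clin_b = nn.Parameter(np.zeros((n_clinical, k)))
            self.cls_clin = nn.Parameter(rng.normal(0.0, 0.02, size=(1, 1, k)))
            self.enc_clin = nn.Encoder(k, config.n_layers, config.n_heads,
                                       config.dropout, rng)
        if len(self.modalities) == 3:
            self.co_gen = nn.CoAttention(k, rng, project=config.coattn_project)
            self.co_img = nn.CoAttention(k, rng, project=config.coattn_project)
            if config.joint == "class_token":
                d_in = 2 * k
            else:
                d_in = (n_roi + 1 + n_snp + 1) * k
            if config.include_clinical_token:
                d_in += k
        else:
            d_in = k
        self.head1 = nn.Linear(d_in, config.mlp_hidden, rng)
        self.head2 = nn.Linear(config.mlp_hidden, config.n_classes, rng)

    # -- tokenizers --------------------------------------------------------
    def tokenize_imaging(self, imaging: np.ndarray) -> nn.Tensor:
        """(b, M, 4) scaled ROI traits -> (b, M, k) tokens, shared affine map."""
        if imaging.ndim != 3 or imaging.shape[-1] != 4:
            raise ValueError(f"imaging input must be (b, M, 4), got {imaging.shape}")
        return self.img_proj(nn.Tensor(imaging))

    def tokenize_genetics(self, snp_input: np.ndarray,
                          chrom: np.ndarray) -> nn.Tensor:
        """(b, N, 4) SNP attributes + (N,) chromosome -> (b, N, k) tokens."""
        if snp_input.ndim != 3 or snp_input.shape[-1] != 4:
            raise ValueError(f"genetics input must be (b, N, 4), got {snp_input.shape}")
        chrom = np.asarray(chrom, dtype=int)
        if chrom.min() < 0 or chrom.max() >= N_CHROMOSOMES:
            raise ValueError(f"chromosome index out of range [0, {N_CHROMOSOMES})")
        b = snp_input.shape[0]
        half = self.snp_proj(nn.Tensor(snp_input))
        emb = self.chrom_emb(chrom).reshape(1, len(chrom), -1)
        emb_b = emb * nn.Tensor(np.ones((b, 1, 1)))
        return nn.cat([half, emb_b], axis=2)

    def tokenize_clinical(self, clinical: np.ndarray) -> nn.Tensor:
        """(b, B) scaled scores -> (b, B, k), independent per-feature maps."""
        if np.isnan(clinical).any():
            raise ValueError("NaN clinical score")
        b, nb = clinical.shape
        x = nn.Tensor(clinical.reshape(b, nb, 1))
        return x * self.clin_w + self.clin_b

    def _with_cls(self, tokens: nn.Tensor, cls: nn.Parameter) -> nn.Tensor:
        b = tokens.shape[0]
        cls_b = cls * nn.Tensor(np.ones((b, 1, 1)))
        return nn.cat([cls_b, tokens], axis=1)

    def _encode(self, modality: str, X: ModalityArrays, idx: np.ndarray) -> nn.Tensor:
        if modality == "imaging":
            t = self.tokenize_imaging(X.imaging[idx])
            return self.enc_img(self._with_cls(t, self.cls_img))
        if modality == "genetics":
            t = self.tokenize_genetics(X.snp_tokens_input()[idx], X.snp_chrom)
            return self.enc_gen(self._with_cls(t, self.cls_gen))
        t = self.tokenize_clinical(X.clinical[idx])
        return self.enc_clin(self._with_cls(t, self.cls_clin))

    # -- forward -----------------------------------------------------------
    def forward(self, X: ModalityArrays, idx: np.ndarray | None = None,
                ) -> tuple[nn.Tensor, dict[str, np.ndarray]]:
        """Class logits and co-attention weight records for a subject batch."""
        if idx is None:
            idx = np.arange(X.n_subjects)
        if len(self.modalities) == 1:
            enc = self._encode(self.modalities[0], X, idx)
            feats = enc[:, 0, :]
            attn: dict[str, np.ndarray] = {}
        else:
            enc_img = self._encode("imaging", X, idx)
            enc_gen = self._encode("genetics", X, idx)
            enc_clin = self._encode("clinical", X, idx)
            out_gen, w_gen = self.co_gen(enc_gen, enc_clin)
            out_img, w_img = self.co_img(enc_img, enc_clin)
            if self.config.joint == "class_token":
                parts = [out_img[:, 0, :], out_gen[:, 0, :]]
            else:
                b = len(idx)
                parts = [out_img.reshape(b, -1), out_gen.reshape(b, -1)]
            if self.config.include_clinical_token:
                parts.append(enc_clin[:, 0, :])
            feats = nn.cat(parts, axis=-1)
            attn = {"imaging": w_img.data, "genetics": w_gen.data}
        logits = self.head2(self.head1(feats).gelu())
        return logits, attn


# ---------------------------------------------------------------------------
# training utilities shared with the deep baselines
# ---------------------------------------------------------------------------

def predict_proba_network(net, X: ModalityArrays, batch_size: int = 256) -> np.ndarray:
    net.eval()
    out = []
    with nn.no_grad():
        for start in range(0, X.n_subjects, batch_size):
            idx = np.arange(start, min(start + batch_size, X.n_subjects))
            logits = net.forward(X, idx)[0].data
            z = logits - logits.max(axis=-1, keepdims=True)
            ez = np.exp(z)
            out.append(ez / ez.sum(axis=-1, keepdims=True))
    return np.concatenate(out, axis=0)


def train_network(net, X: ModalityArrays, y_idx: np.ndarray, *, epochs: int,
                  batch_size: int, learning_rate: float,
                  rng: np.random.Generator, validation=None,
                  eval_every: int = 1) -> dict:
    """Minibatch Adam training with cross-entropy loss.

    If ``validation=(X_val, y_val_idx)`` is given, the epoch with the highest
    validation one-vs-one AUROC is kept (checkpoint selection) and restored
    at the end.  Returns a history dict.
    """
    opt = nn.Adam(net.parameters(), lr=learning_rate)
    n = len(y_idx)
    history: dict = {"loss": [], "val_auroc": []}
    best_score, best_state = -np.inf, None
    n_classes = net.config.n_classes if hasattr(net, "config") else net.n_classes
    for epoch in range(epochs):
        net.train()
        perm = rng.permutation(n)
        total = 0.0
        for start in range(0, n, batch_size):
            idx = perm[start:start + batch_size]
            logits = net.forward(X, idx)[0]
            loss = nn.cross_entropy(logits, y_idx[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data) * len(idx)
        history["loss"].append(total / n)
        if validation is not None and (epoch + 1) % eval_every == 0:
            X_val, y_val = validation
            proba = predict_proba_network(net, X_val, batch_size)
            try:
                score = auroc_ovo(y_val, proba, classes=range(n_classes))
            except ValueError:
                score = np.nan
            history["val_auroc"].append((epoch, score))
            if np.isfinite(score) and score > best_score:
                best_score, best_state = score, net.state()
    if best_state is not None:
        net.load_state(best_state)
        history["best_val_auroc"] = best_score
    net.eval()
    return history


class TriCoatClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn style estimator for the tri-modal co-attention network.

    ``fit`` accepts a :class:`~tricoat.features.ModalityArrays` (already
    scaled) and a label vector; ``validation=(X_val, y_val)`` enables
    best-checkpoint selection by validation OvO AUROC.  With ``modalities``
    restricted to one modality the estimator is the single-modality
    transformer ablation.
    """

    supports_validation = True

    def __init__(self, k: int = 256, n_layers: int = 4, n_heads: int = 4,
                 mlp_hidden: int = 256, learning_rate: float = 1e-4,
                 epochs: int = 100, batch_size: int = 32, dropout: float = 0.1,
                 joint: str = "class_token", coattn_project: bool = True,
                 include_clinical_token: bool = False,
                 modalities: tuple[str, ...] = MODALITIES,
                 eval_every: int = 1, dtype: str = "float32",
                 random_state: int = 0):
        self.k = k
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.mlp_hidden = mlp_hidden
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.dropout = dropout
        self.joint = joint
        self.coattn_project = coattn_project
        self.include_clinical_token = include_clinical_token
        self.modalities = modalities
        self.eval_every = eval_every
        self.dtype = dtype
        self.random_state = random_state

    def _config(self, n_classes: int) -> ModelConfig:
        return ModelConfig(
            k=self.k, n_layers=self.n_layers, n_heads=self.n_heads,
            mlp_hidden=self.mlp_hidden, n_classes=n_classes,
            learning_rate=self.learning_rate, epochs=self.epochs,
            batch_size=self.batch_size, dropout=self.dropout, joint=self.joint,
            coattn_project=self.coattn_project,
            include_clinical_token=self.include_clinical_token,
            seed=self.random_state).validate()

    def _encode_labels(self, y) -> np.ndarray:
        y = np.asarray(y)
        if set(y) <= set(SUBTYPES):
            self.classes_ = np.array([c for c in SUBTYPES if c in set(y)])
        else:
            self.classes_ = np.unique(y)
        lut = {c: i for i, c in enumerate(self.classes_)}
        return np.array([lut[v] for v in y], dtype=np.intp)

    def fit(self, X: ModalityArrays, y, validation=None) -> "TriCoatClassifier":
        y_idx = self._encode_labels(y)
        cfg = self._config(len(self.classes_))
        rng = np.random.default_rng(self.random_state)
        val = None
        if validation is not None:
            X_val, y_val = validation
            lut = {c: i for i, c in enumerate(self.classes_)}
            val = (X_val, np.array([lut[v] for v in np.asarray(y_val)], dtype=np.intp))
        with nn.default_dtype(self.dtype):
            self.network_ = TriCoatNetwork(cfg, len(X.roi_names),
                                           len(X.snp_names),
                                           len(X.clinical_names), rng,
                                           modalities=tuple(self.modalities))
            self.history_ = train_network(
                self.network_, X, y_idx, epochs=cfg.epochs,
                batch_size=cfg.batch_size, learning_rate=cfg.learning_rate,
                rng=rng, validation=val, eval_every=self.eval_every)
        return self

    def predict_proba(self, X: ModalityArrays) -> np.ndarray:
        with nn.default_dtype(self.dtype):
            return predict_proba_network(self.network_, X, self.batch_size)

    def predict(self, X: ModalityArrays) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def attention(self, X: ModalityArrays) -> dict[str, np.ndarray]:
        """Co-attention weights per subject.

        Returns ``{"imaging": (n, M+1, B+1), "genetics": (n, N+1, B+1)}``
        (query tokens x clinical tokens, class token at position 0).
        """
        if len(self.network_.modalities) != 3:
            raise ValueError("attention records require the tri-modal model")
        self.network_.eval()
        recs: dict[str, list[np.ndarray]] = {"imaging": [], "genetics": []}
        with nn.no_grad():
            for start in range(0, X.n_subjects, self.batch_size):
                idx = np.arange(start, min(start + self.batch_size, X.n_subjects))
                _, attn = self.network_.forward(X, idx)
                for m in recs:
                    recs[m].append(attn[m])
        return {m: np.concatenate(v, axis=0) for m, v in recs.items()}

    def get_config(self) -> dict:
        return asdict(self._config(3))


def save_model(est: TriCoatClassifier, path) -> None:
    """Serialize a fitted estimator (params + weights) to an .npz archive."""
    net = est.network_
    arrays = {f"p{i}": p.data for i, p in enumerate(net.parameters())}
    import json
    meta = {"params": est.get_params(), "classes": list(map(str, est.classes_)),
            "dims": {"n_roi": net.n_roi, "n_snp": net.n_snp,
                     "n_clinical": net.n_clinical}}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_model(path) -> TriCoatClassifier:
    """Rebuild a serialized estimator; inverse of :func:`save_model`."""
    import json
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["meta"]))
        weights = [archive[f"p{i}"] for i in range(len(archive.files) - 1)]
    params = meta["params"]
    params["modalities"] = tuple(params["modalities"])
    est = TriCoatClassifier(**params)
    est.classes_ = np.array(meta["classes"])
    cfg = est._config(len(est.classes_))
    dims = meta["dims"]
    est.network_ = TriCoatNetwork(cfg, dims["n_roi"], dims["n_snp"],
                                  dims["n_clinical"],
                                  np.random.default_rng(est.random_state),
                                  modalities=tuple(est.modalities))
    est.network_.load_state(weights)
    est.network_.eval()
    return est
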