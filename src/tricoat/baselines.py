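"""Comparison models: fusion-strategy variants and classical ML baselines.

* Early fusion — all three modalities tokenized into one concatenated token
  sequence with a single shared class token, one transformer encoder, MLP
  head (fusion at the input).
* Late fusion — three independent single-modality transformer branches;
  class probabilities averaged (fusion at the prediction level).
* Stage-wise fusion — intermediate-fusion MLP: one 64-unit layer per
  modality, concatenation, then 32- and 16-unit stages and a linear
  classifier.  Single-modality variant: 64 -> 16 -> logits.
* SVM (RBF kernel, C=1) and random forest (gini, 100 trees, unlimited
  depth) on flattened scaled features; genetics contributes dosages only.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from . import nn
from .data import SUBTYPES
from .features import ModalityArrays
from .model import (MODALITIES, TriCoatClassifier, predict_proba_network,
                    train_network)


def _encode_labels(est, y) -> np.ndarray:
    y = np.asarray(y)
    if set(y) <= set(SUBTYPES):
        est.classes_ = np.array([c for c in SUBTYPES if c in set(y)])
    else:
        est.classes_ = np.unique(y)
    lut = {c: i for i, c in enumerate(est.classes_)}
    return np.array([lut[v] for v in y], dtype=np.intp)


class EarlyFusionClassifier(TriCoatClassifier):
    """Input-level fusion: one encoder over the concatenated token sequence."""

    def fit(self, X: ModalityArrays, y, validation=None) -> "EarlyFusionClassifier":
        y_idx = self._encode_labels(y)
        cfg = self._config(len(self.classes_))
        rng = np.random.default_rng(self.random_state)
        val = None
        if validation is not None:
            X_val, y_val = validation
            lut = {c: i for i, c in enumerate(self.classes_)}
            val = (X_val, np.array([lut[v] for v in np.asarray(y_val)], dtype=np.intp))
        with nn.default_dtype(self.dtype):
            self.network_ = _EarlyFusionNetwork(cfg, len(X.roi_names),
                                                len(X.snp_names),
                                                len(X.clinical_names), rng)
            self.history_ = train_network(
                self.network_, X, y_idx, epochs=cfg.epochs,
                batch_size=cfg.batch_size, learning_rate=cfg.learning_rate,
                rng=rng, validation=val, eval_every=self.eval_every)
        return self

    def attention(self, X):
        raise ValueError("early fusion has no co-attention records")


class _EarlyFusionNetwork(nn.Module):
    def __init__(self, config, n_roi, n_snp, n_clinical, rng):
        from .model import N_CHROMOSOMES
        config.validate()
        self.config = config
        k = config.k
        self.img_proj = nn.Linear(4, k, rng)
        self.snp_proj = nn.Linear(4, k // 2, rng)
        self.chrom_emb = nn.Embedding(N_CHROMOSOMES, k // 2, rng)
        self.clin_w = nn.Parameter(rng.uniform(-1.0, 1.0, size=(n_clinical, k)))
        self.clin_b = nn.Parameter(np.zeros((n_clinical, k)))
        self.cls = nn.Parameter(rng.normal(0.0, 0.02, size=(1, 1, k)))
        self.encoder = nn.Encoder(k, config.n_layers, config.n_heads,
                                  config.dropout, rng)
        self.head1 = nn.Linear(k, config.mlp_hidden, rng)
        self.head2 = nn.Linear(config.mlp_hidden, config.n_classes, rng)

    def forward(self, X: ModalityArrays, idx=None):
        if idx is None:
            idx = np.arange(X.n_subjects)
        b = len(idx)
        img = self.img_proj(nn.Tensor(X.imaging[idx]))
        snp_half = self.snp_proj(nn.Tensor(X.snp_tokens_input()[idx]))
        emb = self.chrom_emb(X.snp_chrom).reshape(1, len(X.snp_chrom), -1)
        gen = nn.cat([snp_half, emb * nn.Tensor(np.ones((b, 1, 1)))], axis=2)
        clin = (nn.Tensor(X.clinical[idx][:, :, None]) * self.clin_w
                + self.clin_b)
        cls_b = self.cls * nn.Tensor(np.ones((b, 1, 1)))
        tokens = nn.cat([cls_b, img, gen, clin], axis=1)
        enc = self.encoder(tokens)
        logits = self.head2(self.head1(enc[:, 0, :]).gelu())
        return logits, {}


class LateFusionClassifier(BaseEstimator, ClassifierMixin):
    """Prediction-level fusion: three single-modality transformer branches
    trained independently; fused class probabilities are the branch mean."""

    supports_validation = True

    def __init__(self, k: int = 256, n_layers: int = 4, n_heads: int = 4,
                 mlp_hidden: int = 256, learning_rate: float = 1e-4,
                 epochs: int = 100, batch_size: int = 32, dropout: float = 0.1,
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
        self.eval_every = eval_every
        self.dtype = dtype
        self.random_state = random_state

    def fit(self, X: ModalityArrays, y, validation=None) -> "LateFusionClassifier":
        _encode_labels(self, y)
        self.branches_ = {}
        for i, modality in enumerate(MODALITIES):
            branch = TriCoatClassifier(
                k=self.k, n_layers=self.n_layers, n_heads=self.n_heads,
                mlp_hidden=self.mlp_hidden, learning_rate=self.learning_rate,
                epochs=self.epochs, batch_size=self.batch_size,
                dropout=self.dropout, modalities=(modality,),
                eval_every=self.eval_every, dtype=self.dtype,
                random_state=self.random_state + i)
            branch.fit(X, y, validation=validation)
            self.branches_[modality] = branch
        return self

    def predict_proba(self, X: ModalityArrays) -> np.ndarray:
        probs = [b.predict_proba(X) for b in self.branches_.values()]
        return np.mean(probs, axis=0)

    def predict(self, X: ModalityArrays) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


class _StagewiseNetwork(nn.Module):
    def __init__(self, modality: str, dims_in: list[int],
                 stage_dims: tuple[int, int, int], n_classes: int, rng):
        d1, d2, d3 = stage_dims
        self.modality = modality
        self.first = [nn.Linear(d, d1, rng) for d in dims_in]
        if len(dims_in) > 1:
            self.mid = nn.Linear(d1 * len(dims_in), d2, rng)
            self.last = nn.Linear(d2, d3, rng)
        else:
            # single-modality variant: first plus last stage only
            self.mid = None
            self.last = nn.Linear(d1, d3, rng)
        self.out = nn.Linear(d3, n_classes, rng)
        self.n_classes = n_classes

    def _blocks_of(self, X: ModalityArrays) -> list[np.ndarray]:
        names = MODALITIES if self.modality == "all" else (self.modality,)
        return [X.flatten(m) for m in names]

    def forward(self, X: ModalityArrays, idx=None):
        blocks = self._blocks_of(X)
        if idx is None:
            idx = np.arange(blocks[0].shape[0])
        hs = [lin(nn.Tensor(blk[idx])).relu()
              for lin, blk in zip(self.first, blocks)]
        h = nn.cat(hs, axis=-1) if len(hs) > 1 else hs[0]
        if self.mid is not None:
            h = self.mid(h).relu()
        h = self.last(h).relu()
        return self.out(h), {}


class StagewiseFusionClassifier(BaseEstimator, ClassifierMixin):
    """Stage-wise intermediate-fusion MLP (64 / 32 / 16 units by default)."""

    supports_validation = True

    def __init__(self, stage_dims: tuple[int, int, int] = (64, 32, 16),
                 modality: str = "all", learning_rate: float = 1e-4,
                 epochs: int = 100, batch_size: int = 32, eval_every: int = 1,
                 dtype: str = "float32", random_state: int = 0):
        self.stage_dims = stage_dims
        self.modality = modality
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.eval_every = eval_every
        self.dtype = dtype
        self.random_state = random_state

    def _blocks_of(self, X: ModalityArrays) -> list[np.ndarray]:
        if self.modality == "all":
            return [X.flatten(m) for m in MODALITIES]
        return [X.flatten(self.modality)]

    def fit(self, X: ModalityArrays, y, validation=None) -> "StagewiseFusionClassifier":
        y_idx = _encode_labels(self, y)
        rng = np.random.default_rng(self.random_state)
        blocks = self._blocks_of(X)
        val = None
        if validation is not None:
            X_val, y_val = validation
            lut = {c: i for i, c in enumerate(self.classes_)}
            val = (X_val, np.array([lut[v] for v in np.asarray(y_val)], dtype=np.intp))
        with nn.default_dtype(self.dtype):
            self.network_ = _StagewiseNetwork(self.modality,
                                              [b.shape[1] for b in blocks],
                                              tuple(self.stage_dims),
                                              len(self.classes_), rng)
            self.history_ = train_network(
                self.network_, X, y_idx, epochs=self.epochs,
                batch_size=self.batch_size, learning_rate=self.learning_rate,
                rng=rng, validation=val, eval_every=self.eval_every)
        return self

    def predict_proba(self, X: ModalityArrays) -> np.ndarray:
        return predict_proba_network(self.network_, X, self.batch_size)

    def predict(self, X: ModalityArrays) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


class FlatFeatureClassifier(BaseEstimator, ClassifierMixin):
    """Adapter running a scikit-learn classifier on flattened features."""

    supports_validation = False

    def __init__(self, method: str = "svm", modality: str = "all",
                 random_state: int = 0):
        self.method = method
        self.modality = modality
        self.random_state = random_state

    def _make(self):
        if self.method == "svm":
            return SVC(kernel="rbf", C=1.0, probability=True,
                       random_state=self.random_state)
        if self.method == "rf":
            return RandomForestClassifier(n_estimators=100, criterion="gini",
                                          max_depth=None,
                                          random_state=self.random_state)
        raise ValueError(f"unknown method {self.method!r}")

    def fit(self, X: ModalityArrays, y) -> "FlatFeatureClassifier":
        self.model_ = self._make().fit(X.flatten(self.modality), np.asarray(y))
        self.classes_ = self.model_.classes_
        return self

    def predict_proba(self, X: ModalityArrays) -> np.ndarray:
        return self.model_.predict_proba(X.flatten(self.modality))

    def predict(self, X: ModalityArrays) -> np.ndarray:
        return self.model_.predict(X.flatten(self.modality))


# ---------------------------------------------------------------------------
# factory functions
# ---------------------------------------------------------------------------

def build_single_modality(modality: str, method: str = "tricoat", **kwargs):
    """Single-modality ablation of a given method."""
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}")
    if method == "tricoat":
        return TriCoatClassifier(modalities=(modality,), **kwargs)
    if method == "stagewise":
        return StagewiseFusionClassifier(modality=modality, **kwargs)
    if method in ("svm", "rf"):
        return FlatFeatureClassifier(method=method, modality=modality, **kwargs)
    raise ValueError(f"unknown method {method!r}")


def build_early_fusion(**kwargs) -> EarlyFusionClassifier:
    return EarlyFusionClassifier(**kwargs)


def build_late_fusion(**kwargs) -> LateFusionClassifier:
    return LateFusionClassifier(**kwargs)


def build_stagewise_fusion(**kwargs) -> StagewiseFusionClassifier:
    return StagewiseFusionClassifier(**kwargs)
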