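# tricoat

Tri-modal co-attention (Tri-COAT) classification of progression-specific
Alzheimer's disease subtypes from **baseline** imaging, genotype and
clinical data — with the full surrounding pipeline: MMSE-trajectory subtype
labelling, a synthetic cohort generator with planted class structure,
fusion-strategy baselines, a nested cross-testing harness, and
co-attention-based cross-modal interpretation.

## Who this is for

Researchers studying disease heterogeneity who want to (a) assign
slow/intermediate/fast cognitive-decline subtypes from longitudinal MMSE
scores, (b) predict those subtypes from baseline multimodal data with a
transformer that explicitly models cross-modal feature associations, and
(c) benchmark that model against early/late/intermediate fusion and
classical ML under a leakage-safe nested evaluation protocol.  Real cohort
data of this kind (e.g. ADNI) are controlled-access, so the package ships a
synthetic generator that reproduces every table schema and plants tunable
class signal, making the whole pipeline testable end to end.

## The model

Each modality becomes a token sequence: one token per cortical ROI (4
morphometric traits, shared affine map to width *k*), per SNP (dosage +
GWAS odds ratio, rare-allele frequency and intergenic flag mapped to *k*/2,
concatenated with a learned chromosome embedding), and per clinical score
(independent 1→*k* maps).  With a prepended class token, each sequence runs
through its own pre-LN transformer encoder

```
F'_l = MHA(LN(F_{l-1})) + F_{l-1}
F_l  = FF(LN(F'_l))     + F'_l
```

Encoded genetics and imaging tokens then **co-attend** to the encoded
clinical tokens (single head):

```
CoAttn(Q_{G,I}, C) = softmax(Q_{G,I} K_C^T / sqrt(d_k)) V_C
```

so each ROI/SNP re-weights the clinical representation through its learned
clinical associations.  The two co-attended class tokens are concatenated
and classified into three subtypes by a one-hidden-layer MLP trained with
cross-entropy.  The co-attention weight matrices double as the model's
interpretation output.

Subtype labels come from k-means (k=3) on baseline-anchored MMSE deltas at
6/12/24 months, with clusters named slow/intermediate/fast by their
24-month centroid.  Evaluation uses 10-fold stratified cross-testing with
inner 5-fold validation for hyperparameter/checkpoint selection (50
evaluations per method) and one-vs-one (Hand–Till) multiclass AUROC.

The network runs on a small numpy reverse-mode autodiff core shipped with
the package (`tricoat.nn`) — no deep-learning framework required.

## Worked example

```python
import pandas as pd
from tricoat import (CohortSpec, simulate_cohort, compute_deltas,
                     cluster_subtypes, fit_scaler, tensorize,
                     TriCoatClassifier, auroc_ovo)
from sklearn.model_selection import train_test_split

# cohort with published class sizes and strong planted signal
cohort, truth = simulate_cohort(CohortSpec(effect_size=2.0, seed=5))

# label subtypes from MMSE trajectories
labeling = cluster_subtypes(compute_deltas(cohort.mmse), seed=0)
print(labeling.centroids.round(2))

# train on baseline data only, score held-out subjects
labels = labeling.labels
tr, te = train_test_split(cohort.subjects.to_numpy(), test_size=0.25,
                          stratify=labels, random_state=0)
arrays = tensorize(fit_scaler(cohort, pd.Index(tr)).transform(cohort))
clf = TriCoatClassifier(k=64, n_layers=2, n_heads=4, mlp_hidden=128,
                        learning_rate=1e-3, epochs=12, batch_size=64,
                        random_state=0)
clf.fit(arrays.loc(tr), labels.loc[tr].to_numpy())
auc = auroc_ovo(labels.loc[te].to_numpy(),
                clf.predict_proba(arrays.loc(te)), classes=clf.classes_)
print(f"held-out OvO AUROC: {auc:.3f}")
```

This prints the cluster centroid table and the held-out score:

```
                6     12    24
subtype
slow          0.22  0.53  0.54
intermediate -1.60 -2.57 -3.88
fast         -5.56 -7.00 -8.88
held-out OvO AUROC: 0.895
```

The centroids recover the planted trajectory means (slow is stable with a
small practice-effect gain; fast loses ~9 MMSE points by 24 months), and
the baseline-only classifier separates the k-means-derived subtypes well —
not perfectly, because the prediction target is the *clustered* label,
which itself differs from the planted class for boundary subjects.
Attention-based interpretation:

```python
from tricoat import average_attention, export_chord_edges
attn = clf.attention(arrays.loc(te))
table = average_attention(attn, arrays.roi_names, arrays.snp_names,
                          arrays.clinical_names)
print(export_chord_edges(table, top_k=3))
#        from               to     value
# 0  rs100004        DIGITSCOR  0.270674
# 1  rs100060        DIGITSCOR  0.270640
# 2  rs100041        DIGITSCOR  0.270442
# 3    ROI011  RAVLT_immediate  0.585431
# 4    ROI005  RAVLT_immediate  0.583249
# 5    ROI060  RAVLT_immediate  0.582510
```

There is also a CLI covering the same pipeline stage by stage:

```bash
tricoat simulate --out data/ --seed 3
tricoat label --mmse data/mmse.csv --out labels.csv --seed 0
tricoat evaluate --data data/ --labels labels.csv --out eval/ \
        --methods svm,rf --seed 1
tricoat train --data data/ --labels labels.csv --out run/ --epochs 20 --k 64
tricoat interpret --run run/ --data data/ --top-k 10
```

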