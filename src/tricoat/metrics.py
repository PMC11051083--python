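"""Multiclass ranking metric: one-vs-one AUROC (Hand & Till construction).

For every unordered class pair (a, b) the subjects of those two classes are
extracted and two directed AUCs are computed — ranking a against b by the
class-a probability column, and b against a by the class-b column.  The pair
score is their average, and the overall score the unweighted mean over the
three pairs.  Ties contribute 1/2 (Mann-Whitney convention).
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import rankdata


def _binary_auc(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """AUC of positives vs negatives from the Mann-Whitney U statistic."""
    n_pos, n_neg = len(scores_pos), len(scores_neg)
    ranks = rankdata(np.concatenate([scores_pos, scores_neg]))
    u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def auroc_ovo(y_true, proba: np.ndarray, classes=None) -> float:
    """One-vs-one multiclass AUROC.

    Parameters
    ----------
    y_true : array of class labels (any hashable values).
    proba : (n, C) array; column j is the predicted probability of
        ``classes[j]``.
    classes : label order matching the columns of ``proba``; defaults to
        sorted unique labels of ``y_true``.

    Raises
    ------
    ValueError if some class pair has no members of one class, which leaves
    that pair's AUC (and hence the average) undefined.
    """
    y_true = np.asarray(y_true)
    proba = np.asarray(proba, dtype=float)
    if classes is None:
        classes = np.unique(y_true)
    classes = list(classes)
    if proba.ndim != 2 or proba.shape[1] != len(classes):
        raise ValueError("proba must be (n_subjects, n_classes)")
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    pair_scores = []
    for (ia, a), (ib, b) in itertools.combinations(enumerate(classes), 2):
        mask_a = y_true == a
        mask_b = y_true == b
        if not mask_a.any() or not mask_b.any():
            raise ValueError(f"AUROC undefined: pair ({a!r}, {b!r}) lacks a class")
        auc_a = _binary_auc(proba[mask_a, ia], proba[mask_b, ia])
        auc_b = _binary_auc(proba[mask_b, ib], proba[mask_a, ib])
        pair_scores.append(0.5 * (auc_a + auc_b))
    return float(np.mean(pair_scores))


def null_auroc_se(y_true, classes=None) -> float:
    """Conservative standard error of the OvO AUROC under label-independent
    scores: the largest per-pair null SE, sqrt((nA+nB+1)/(12 nA nB))."""
    y_true = np.asarray(y_true)
    if classes is None:
        classes = np.unique(y_true)
    ses = []
    for a, b in itertools.combinations(classes, 2):
        na = int((y_true == a).sum())
        nb = int((y_true == b).sum())
        ses.append(np.sqrt((na + nb + 1) / (12.0 * na * nb)))
    return float(max(ses))
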