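"""Progression-subtype definition from MMSE trajectories.

Each subject's follow-up MMSE scores are anchored to baseline (baseline
subtracted from the 6/12/24-month visits, so every subject starts at 0) and
the resulting 3-dimensional delta vectors are clustered with k-means, k=3.
Clusters are then named by their 24-month centroid delta: the least declining
cluster is *slow*, the most declining *fast*, the remaining one
*intermediate*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .data import MMSE_VISITS, SUBTYPES

logger = logging.getLogger(__name__)

FOLLOWUP_VISITS = MMSE_VISITS[1:]  # (6, 12, 24) months


def compute_deltas(mmse: pd.DataFrame) -> pd.DataFrame:
    """Baseline-anchored MMSE deltas.

    Parameters
    ----------
    mmse : DataFrame indexed by subject with columns 0/6/12/24 (months).
        Baseline (month 0) must be present for every subject; subjects
        missing any follow-up are excluded and logged.

    Returns
    -------
    DataFrame indexed by the complete subjects, columns 6/12/24, values
    MMSE(visit) - MMSE(baseline).
    """
    if mmse[0].isna().any():
        missing = mmse.index[mmse[0].isna()]
        raise ValueError(f"baseline MMSE missing for subjects {list(missing[:5])}")
    complete = mmse[FOLLOWUP_VISITS].notna().all(axis=1)
    if (~complete).any():
        logger.info("compute_deltas: excluding %d subject(s) with incomplete "
                    "follow-up", int((~complete).sum()))
    kept = mmse.loc[complete]
    if kept.empty:
        raise ValueError("no subject has complete 6/12/24-month follow-up")
    deltas = kept[FOLLOWUP_VISITS].sub(kept[0], axis=0)
    return deltas.sort_index()


@dataclass
class SubtypeLabeling:
    """Result of the k-means subtype assignment."""

    labels: pd.Series                 # subject -> slow/intermediate/fast
    centroids: pd.DataFrame           # index subtype, columns 6/12/24
    cluster_to_label: dict[int, str]  # raw k-means cluster id -> subtype
    inertia: float


class SubtypeLabeler(BaseEstimator):
    """K-means (k=3) clusterer over baseline-anchored MMSE deltas.

    Uses k-means++ initialization with ``n_init`` restarts and tolerance
    ``tol`` on centroid movement.  Rows are sorted by subject ID before
    clustering so the result is invariant to input order.
    """

    def __init__(self, n_clusters: int = 3, n_init: int = 10, tol: float = 1e-6,
                 random_state: int = 0):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.tol = tol
        self.random_state = random_state

    def fit(self, deltas: pd.DataFrame) -> "SubtypeLabeler":
        deltas = deltas.sort_index()
        X = deltas.to_numpy(dtype=float)
        if len(np.unique(X, axis=0)) < self.n_clusters:
            raise ValueError(
                f"need >= {self.n_clusters} distinct delta vectors to cluster")
        km = KMeans(n_clusters=self.n_clusters, init="k-means++",
                    n_init=self.n_init, tol=self.tol,
                    random_state=self.random_state)
        raw = km.fit_predict(X)
        order = np.argsort(-km.cluster_centers_[:, -1])  # 24-month delta desc
        mapping = {int(cluster): SUBTYPES[rank]
                   for rank, cluster in enumerate(order)}
        labels = pd.Series([mapping[c] for c in raw], index=deltas.index,
                           name="subtype")
        centroids = pd.DataFrame(
            km.cluster_centers_[order], index=pd.Index(SUBTYPES, name="subtype"),
            columns=deltas.columns)
        self.labeling_ = SubtypeLabeling(labels=labels, centroids=centroids,
                                         cluster_to_label=mapping,
                                         inertia=float(km.inertia_))
        self.labels_ = labels
        self.cluster_centers_ = centroids
        return self

    def fit_predict(self, deltas: pd.DataFrame) -> pd.Series:
        return self.fit(deltas).labels_


def cluster_subtypes(deltas: pd.DataFrame, seed: int = 0) -> SubtypeLabeling:
    """Cluster delta vectors into slow/intermediate/fast subtypes."""
    return SubtypeLabeler(random_state=seed).fit(deltas).labeling_


def label_cohort(mmse: pd.DataFrame, seed: int = 0) -> SubtypeLabeling:
    """Convenience: deltas + clustering in one call."""
    return cluster_subtypes(compute_deltas(mmse), seed=seed)
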