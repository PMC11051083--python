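"""Cross-modal attention interpretation.

Co-attention weights (query-modality tokens x clinical tokens) from a
trained model are averaged over a set of test subjects into an association
table naming ROI/SNP-to-clinical-feature links, and the strongest links are
exported as a chord-plot edge list (from, to, value) consumable by
circlize-style plotting.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def average_attention(attention: dict[str, np.ndarray], roi_names: list[str],
                      snp_names: list[str], clinical_names: list[str],
                      exclude_class_token: bool = True) -> pd.DataFrame:
    """Average per-subject co-attention weights into an association table.

    Parameters
    ----------
    attention : ``{"imaging": (n, M+1, B+1), "genetics": (n, N+1, B+1)}``
        weight stacks with the class token at index 0 of both axes.
    exclude_class_token : drop class-token rows/columns and renormalize each
        query row over the clinical features before averaging (class tokens
        aggregate rather than associate).

    Returns
    -------
    DataFrame with columns query_modality, query, clinical, weight; for each
    query token the weights over clinical features sum to 1.
    """
    names = {"imaging": roi_names, "genetics": snp_names}
    rows = []
    for modality, stack in attention.items():
        stack = np.asarray(stack)
        if stack.ndim != 3 or stack.shape[0] == 0:
            raise ValueError(f"{modality}: need a nonempty (n, Q, C) weight stack")
        if exclude_class_token:
            w = stack[:, 1:, 1:]
            w = w / w.sum(axis=2, keepdims=True)
            q_names, c_names = names[modality], clinical_names
        else:
            w = stack
            q_names = ["<cls>"] + names[modality]
            c_names = ["<cls>"] + clinical_names
        if w.shape[1] != len(q_names) or w.shape[2] != len(c_names):
            raise ValueError(f"{modality}: weight shape {w.shape[1:]} does not "
                             f"match {len(q_names)} query x {len(c_names)} "
                             "clinical names")
        mean = w.mean(axis=0)
        for i, qn in enumerate(q_names):
            for j, cn in enumerate(c_names):
                rows.append({"query_modality": modality, "query": qn,
                             "clinical": cn, "weight": mean[i, j]})
    return pd.DataFrame(rows)


def export_chord_edges(table: pd.DataFrame, top_k: int,
                       path: str | Path | None = None) -> pd.DataFrame:
    """Select the ``top_k`` strongest edges per query modality.

    Ties break deterministically by (weight desc, from asc, to asc).  Writes
    a CSV with columns from, to, value if ``path`` is given.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    edges = []
    for modality, sub in table.groupby("query_modality", sort=True):
        k = top_k
        if k > len(sub):
            warnings.warn(f"top_k={top_k} exceeds {len(sub)} edges for "
                          f"{modality}; clamping", UserWarning, stacklevel=2)
            k = len(sub)
        ranked = sub.assign(neg=-sub["weight"]).sort_values(
            ["neg", "query", "clinical"]).head(k)
        edges.append(ranked[["query", "clinical", "weight"]])
    out = pd.concat(edges, ignore_index=True)
    out.columns = ["from", "to", "value"]
    if path is not None:
        out.to_csv(path, index=False)
    return out
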