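"""Gene prioritization by the RNs score.

RNs = K * Rs / L, where K is a node's degree, L its total shortest-path
length to the other nodes of its component, and Rs an SVM-RFE rank score:
features are eliminated one at a time by smallest squared weight of a
linear SVM, and the gene eliminated last (rank 1) receives Rs = n, the
first-eliminated Rs = 1. The score blends discriminative expression with
topological centrality: K/L is exactly closeness divided by (N_c - 1)-th,
so RNs rewards hubs that sit centrally and separate the stage groups.
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

__all__ = ["svm_rfe_rank", "rns_scores", "top_genes", "log2_zscore"]


def log2_zscore(expr: pd.DataFrame) -> pd.DataFrame:
    """log2(x + 1) then per-gene standardization — the expression scale fed
    to the SVM."""
    x = np.log2(expr.to_numpy(dtype=float) + 1.0)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0.0] = 1.0
    return pd.DataFrame((x - mu) / sd, index=expr.index, columns=expr.columns)


def svm_rfe_rank(
    expr: pd.DataFrame,
    labels: Sequence[str],
    C: float = 1.0,
    step: int = 1,
    transform: bool = True,
) -> pd.DataFrame:
    """Recursive feature elimination with a linear SVM.

    ``expr`` is genes x samples (raw counts when ``transform`` is True).
    At each iteration the ``step`` features with the smallest squared
    weights are removed (ties broken lexicographically by gene id so the
    ranking is deterministic). Returns a table with ``rfe_rank`` (1 =
    eliminated last) and ``Rs = n_features - rfe_rank + 1``.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) != 2:
        raise ValueError("need exactly two classes")
    if expr.shape[0] < 2:
        raise ValueError("need >= 2 genes")
    X = (log2_zscore(expr) if transform else expr).to_numpy(dtype=float).T
    genes = list(expr.index)
    n = len(genes)
    remaining = list(range(n))
    elimination_order: List[int] = []  # first-eliminated first
    while remaining:
        if len(remaining) == 1:
            elimination_order.append(remaining.pop())
            break
        clf = SVC(kernel="linear", C=C)
        clf.fit(X[:, remaining], y)
        w2 = np.square(np.asarray(clf.coef_).ravel())
        order = sorted(range(len(remaining)), key=lambda j: (w2[j], genes[remaining[j]]))
        k = min(step, len(remaining) - 1)
        doomed = sorted(order[:k], reverse=True)
        for j in doomed:
            elimination_order.append(remaining.pop(j))
    rank = np.empty(n, dtype=int)
    for pos, idx in enumerate(elimination_order):
        rank[idx] = n - pos  # last eliminated gets rank 1
    return pd.DataFrame(
        {"gene_id": genes, "rfe_rank": rank, "Rs": n - rank + 1}
    ).set_index("gene_id")


def rns_scores(topology: pd.DataFrame, ranking: pd.DataFrame) -> pd.DataFrame:
    """Combine node topology with the RFE ranking into the RNs table.

    ``topology`` is indexed by node id with columns D, L (from
    :func:`gcpmir.network.compute_topology`); ``ranking`` is indexed by
    gene id with column Rs. Genes missing from the network, or flagged as
    excluded singletons, are dropped with a warning. Sorted by descending
    RNs; rounding to 3 decimals happens only at report time.
    """
    import warnings

    common = ranking.index.intersection(topology.index)
    missing = ranking.index.difference(topology.index)
    if len(missing):
        warnings.warn(f"genes absent from network excluded: {list(missing)}")
    topo = topology.loc[common]
    if "excluded" in topo.columns and topo["excluded"].any():
        warnings.warn(
            f"singleton nodes excluded: {list(topo.index[topo['excluded']])}"
        )
        topo = topo[~topo["excluded"]]
    K = topo["D"].to_numpy(dtype=float)
    L = topo["L"].to_numpy(dtype=float)
    assert (L > 0).all(), "connected nodes must have positive L"
    rs = ranking.loc[topo.index, "Rs"].to_numpy(dtype=float)
    out = pd.DataFrame(
        {"K": K.astype(int), "L": L.astype(int), "Rs": rs, "RNs": K * rs / L},
        index=topo.index,
    )
    out.index.name = "gene_id"
    return out.sort_values("RNs", ascending=False)


def top_genes(
    rns_table: pd.DataFrame, k: int, exclude: Iterable[str] = ()
) -> List[str]:
    """Top-k genes by RNs after removing excluded ids.

    Ties in RNs break toward the higher-degree gene, then lexicographic id.
    """
    if k > len(rns_table):
        raise ValueError("k exceeds table size")
    tab = rns_table.drop(index=[g for g in exclude if g in rns_table.index]).copy()
    tab["_id"] = tab.index.astype(str)  # lexicographic tie-break
    tab = tab.sort_values(
        by=["RNs", "K", "_id"], ascending=[False, False, True], kind="mergesort"
    )
    return list(tab.index[:k])
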