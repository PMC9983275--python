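"""Construction and topology of the progression-specific miRNA-mediated network.

The network is built in four steps from stage-differential genes:

1. score every miRNA x partner (mRNA or lncRNA) pair with a Spearman
   correlation and keep pairs with p < 0.05;
2. keep miRNA-mRNA edges with SCC < -0.3 that are also predicted with
   score > 50;
3. keep miRNA-lncRNA edges with SCC < -0.3, or SCC < 0 when predicted by
   at least one database-like source;
4. the ceRNA closure: retain only miRNAs with at least one mRNA and at
   least one lncRNA partner, their incident edges, and their endpoints.

All thresholds use strict inequalities. Node topology (degree D, total
shortest-path length L, closeness C = (N_c - 1)/L, normalized betweenness
B) is computed per connected component on the unweighted undirected graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NetworkThresholds",
    "spearman_edges",
    "build_network",
    "compute_topology",
]


@dataclass
class NetworkThresholds:
    """Edge-retention thresholds (all strict)."""

    corr_p_max: float = 0.05
    scc_mrna: float = -0.3
    evidence_score_min: float = 50.0
    scc_lncrna: float = -0.3
    scc_lncrna_predicted: float = 0.0


def _rankdata_rows(x: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, x)


def spearman_edges(
    expr_mirna: pd.DataFrame,
    expr_partner: pd.DataFrame,
    partner_class: str,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlation for every miRNA x partner pair.

    Average-rank ties; two-sided p from the t approximation with n - 2 df.
    Pairs with p >= ``p_max`` are dropped; constant genes are skipped with a
    warning. Both matrices must share the same sample columns.
    """
    if list(expr_mirna.columns) != list(expr_partner.columns):
        raise ValueError("sample columns differ between the two matrices")
    n = expr_mirna.shape[1]
    if n < 10:
        raise ValueError("need >= 10 shared samples for correlation filtering")
    xm = expr_mirna.to_numpy(dtype=float)
    xp = expr_partner.to_numpy(dtype=float)
    const_m = np.ptp(xm, axis=1) == 0.0
    const_p = np.ptp(xp, axis=1) == 0.0
    if const_m.any() or const_p.any():
        skipped = list(expr_mirna.index[const_m]) + list(expr_partner.index[const_p])
        warnings.warn(f"constant expression, pairs skipped for: {skipped}")
    rm = _rankdata_rows(xm[~const_m])
    rp = _rankdata_rows(xp[~const_p])
    rm = (rm - rm.mean(axis=1, keepdims=True)) / rm.std(axis=1, keepdims=True)
    rp = (rp - rp.mean(axis=1, keepdims=True)) / rp.std(axis=1, keepdims=True)
    rho = rm @ rp.T / n
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    mirna_ids = expr_mirna.index[~const_m]
    partner_ids = expr_partner.index[~const_p]
    ii, jj = np.nonzero(p < p_max)
    return pd.DataFrame(
        {
            "mirna_id": mirna_ids[ii],
            "partner_id": partner_ids[jj],
            "partner_class": partner_class,
            "scc": rho[ii, jj],
            "p_value": p[ii, jj],
        }
    ).reset_index(drop=True)


def build_network(
    de_direction: pd.Series,
    corr_edges: pd.DataFrame,
    evidence_mrna: pd.DataFrame,
    evidence_lncrna: pd.DataFrame,
    thresholds: Optional[NetworkThresholds] = None,
    cerna_closure: bool = True,
    node_class: Optional[pd.Series] = None,
) -> nx.Graph:
    """Assemble the typed undirected network from correlation + evidence.

    ``de_direction`` maps gene id -> "up"/"down" (the DE candidates);
    ``corr_edges`` is the p-filtered output of :func:`spearman_edges` for
    both partner classes; evidence tables follow the generator's layout.
    ``node_class`` maps gene id -> RNA class and is needed only for nodes
    absent from ``corr_edges`` metadata (normally inferred).

    The graph carries ``status`` in ``G.graph``: "ok" or "empty_network".
    Every edge touches exactly one miRNA by construction.
    """
    th = thresholds or NetworkThresholds()
    scored = {
        (r.mirna_id, r.target_id): float(r.score) for r in evidence_mrna.itertuples()
    }
    predicted_lnc = set(zip(evidence_lncrna["mirna_id"], evidence_lncrna["target_id"]))

    g = nx.Graph(status="ok")
    for row in corr_edges.itertuples():
        if row.mirna_id not in de_direction.index or row.partner_id not in de_direction.index:
            continue
        keep = False
        evidence_flag = ""
        if row.partner_class == "mRNA":
            score = scored.get((row.mirna_id, row.partner_id))
            if (
                row.scc < th.scc_mrna
                and score is not None
                and score > th.evidence_score_min
            ):
                keep = True
                evidence_flag = f"score={score:.1f}"
        elif row.partner_class == "lncRNA":
            predicted = (row.mirna_id, row.partner_id) in predicted_lnc
            if row.scc < th.scc_lncrna:
                keep = True
                evidence_flag = "corr"
            elif row.scc < th.scc_lncrna_predicted and predicted:
                keep = True
                evidence_flag = "predicted"
        else:
            raise ValueError(f"unknown partner class {row.partner_class!r}")
        if keep:
            g.add_node(
                row.mirna_id, klass="miRNA", de_direction=de_direction[row.mirna_id]
            )
            g.add_node(
                row.partner_id,
                klass=row.partner_class,
                de_direction=de_direction[row.partner_id],
            )
            g.add_edge(
                row.mirna_id,
                row.partner_id,
                scc=float(row.scc),
                p_value=float(row.p_value),
                evidence=evidence_flag,
            )

    if cerna_closure:
        keep_mirnas = set()
        for node, data in g.nodes(data=True):
            if data["klass"] != "miRNA":
                continue
            classes = {g.nodes[nb]["klass"] for nb in g.neighbors(node)}
            if "mRNA" in classes and "lncRNA" in classes:
                keep_mirnas.add(node)
        drop = [
            n for n, d in g.nodes(data=True) if d["klass"] == "miRNA" and n not in keep_mirnas
        ]
        g.remove_nodes_from(drop)
        g.remove_nodes_from([n for n in g.nodes if g.degree(n) == 0])

    for u, v in g.edges:
        ku, kv = g.nodes[u]["klass"], g.nodes[v]["klass"]
        assert (ku == "miRNA") != (kv == "miRNA"), "edge must touch exactly one miRNA"
    if g.number_of_nodes() == 0:
        g.graph["status"] = "empty_network"
    return g


def compute_topology(net: nx.Graph) -> pd.DataFrame:
    """Per-node degree D, total shortest-path length L, closeness
    C = (N_c - 1)/L and betweenness B normalized by (N_c - 1)(N_c - 2)/2,
    all within the node's connected component.

    Singleton components have no defined closeness; those nodes are
    returned with ``excluded=True`` and NaN metrics.
    """
    if net.number_of_nodes() < 2:
        raise ValueError("need a network with >= 2 nodes")
    rows = []
    for comp in nx.connected_components(net):
        sub = net.subgraph(comp)
        nc = sub.number_of_nodes()
        if nc == 1:
            (node,) = comp
            rows.append((node, net.degree(node), np.nan, np.nan, np.nan, 1, True))
            continue
        btw = nx.betweenness_centrality(sub, normalized=True)
        for node in sub.nodes:
            dist = nx.single_source_shortest_path_length(sub, node)
            L = sum(dist.values())
            rows.append(
                (node, sub.degree(node), L, (nc - 1) / L, btw[node], nc, False)
            )
    out = pd.DataFrame(
        rows, columns=["node_id", "D", "L", "C", "B", "component_size", "excluded"]
    )
    return out.set_index("node_id")
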