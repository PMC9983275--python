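"""Family-anchored module extraction and expression-level validation.

The module rule: starting from the prioritized miRNAs (tagged with their
family) and lncRNAs, add every network mRNA adjacent to at least one member
of *each* family, then restrict edges to the members. Validation recomputes
Spearman correlations per module edge on an independent expression set
(green = SCC < -0.5 and p < 0.05, both strict) and contrasts each gene's
expression between sample groups with a two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ProgressionModule", "extract_module", "validate_module"]

GREEN_SCC = -0.5
GREEN_P = 0.05


@dataclass
class ProgressionModule:
    """Module membership plus its induced edges."""

    mirnas: Dict[str, str]  # miRNA id -> family tag
    lncrnas: List[str]
    mrnas: List[str]
    edges: List[Tuple[str, str]]  # (mirna, partner)

    def __post_init__(self) -> None:
        members = set(self.mirnas) | set(self.lncrnas) | set(self.mrnas)
        for u, v in self.edges:
            if u not in members or v not in members:
                raise ValueError(f"edge ({u}, {v}) leaves the module")

    @property
    def genes(self) -> List[str]:
        return list(self.mirnas) + list(self.lncrnas) + list(self.mrnas)

    @property
    def families(self) -> List[str]:
        return sorted(set(self.mirnas.values()))


def extract_module(
    net: nx.Graph,
    selected: Sequence[str],
    family_map: Mapping[str, str],
    min_edges_per_family: int = 1,
) -> ProgressionModule:
    """Build the module from prioritized genes.

    ``selected`` holds the prioritized miRNAs and lncRNAs (all must be
    network nodes); ``family_map`` assigns each selected miRNA to a family.
    An mRNA joins the module iff it has >= ``min_edges_per_family`` edges
    to members of every family. Raises if any family ends up empty (the
    rule is undefined without both anchors).
    """
    for g in selected:
        if g not in net:
            raise ValueError(f"selected gene {g!r} is not in the network")
    sel_mirnas = {g: family_map[g] for g in selected if net.nodes[g]["klass"] == "miRNA"}
    sel_lncrnas = [g for g in selected if net.nodes[g]["klass"] == "lncRNA"]
    families = sorted(set(sel_mirnas.values()))
    for fam in sorted(set(family_map.values())):
        if fam not in families:
            raise ValueError(f"family {fam!r} has no selected member; rule undefined")
    if len(families) < 2:
        raise ValueError("module rule needs at least two anchored families")

    fam_members: Dict[str, List[str]] = {f: [] for f in families}
    for m, f in sel_mirnas.items():
        fam_members[f].append(m)
    mrnas = []
    for node, data in net.nodes(data=True):
        if data["klass"] != "mRNA":
            continue
        nbrs = set(net.neighbors(node))
        if all(
            len(nbrs.intersection(members)) >= min_edges_per_family
            for members in fam_members.values()
        ):
            mrnas.append(node)
    members = set(sel_mirnas) | set(sel_lncrnas) | set(mrnas)
    edges = [
        (u, v) if net.nodes[u]["klass"] == "miRNA" else (v, u)
        for u, v in net.edges
        if u in members and v in members
    ]
    module = ProgressionModule(
        mirnas=sel_mirnas, lncrnas=sorted(sel_lncrnas), mrnas=sorted(mrnas), edges=sorted(edges)
    )
    # closure invariant: every module mRNA touches every family
    for t in module.mrnas:
        touched = {sel_mirnas[m] for m, p in module.edges if p == t}
        assert touched == set(families), "module closure violated"
    return module


def validate_module(
    module: ProgressionModule,
    expr_validation: pd.DataFrame,
    contrasts: Optional[Mapping[str, pd.Series]] = None,
    green_scc: float = GREEN_SCC,
    green_p: float = GREEN_P,
) -> Dict[str, pd.DataFrame]:
    """Re-test the module's structure on an independent expression matrix.

    ``expr_validation`` is genes x samples covering (ideally) all module
    genes; missing genes are reported, not silently dropped. ``contrasts``
    maps a contrast name (e.g. "GC_vs_NT") to a per-sample label Series
    with exactly two levels.

    Returns ``{"edges": ..., "genes": ..., "missing": ...}``: per-edge SCC,
    p and the strict green flag; per-gene Wilcoxon rank-sum W and p per
    contrast; and the list of missing genes.
    """
    present = set(expr_validation.index)
    missing = [g for g in module.genes if g not in present]
    edge_rows = []
    for mirna, partner in module.edges:
        if mirna in present and partner in present:
            rho, p = stats.spearmanr(
                expr_validation.loc[mirna], expr_validation.loc[partner]
            )
            edge_rows.append(
                (mirna, partner, rho, p, bool(rho < green_scc and p < green_p))
            )
        else:
            edge_rows.append((mirna, partner, np.nan, np.nan, False))
    edges = pd.DataFrame(
        edge_rows, columns=["mirna_id", "partner_id", "scc", "p_value", "green"]
    )

    gene_rows = []
    for name, labels in (contrasts or {}).items():
        labels = pd.Series(labels).reindex(expr_validation.columns)
        levels = sorted(labels.dropna().unique())
        if len(levels) != 2:
            raise ValueError(f"contrast {name!r} must have two levels, got {levels}")
        a_cols = labels == levels[0]
        b_cols = labels == levels[1]
        for g in module.genes:
            if g not in present:
                continue
            x = expr_validation.loc[g, a_cols.to_numpy()].to_numpy(dtype=float)
            y = expr_validation.loc[g, b_cols.to_numpy()].to_numpy(dtype=float)
            if np.ptp(np.concatenate([x, y])) == 0.0:
                gene_rows.append((name, g, np.nan, 1.0))
                continue
            res = stats.mannwhitneyu(x, y, alternative="two-sided")
            gene_rows.append((name, g, float(res.statistic), float(res.pvalue)))
    genes = pd.DataFrame(gene_rows, columns=["contrast", "gene_id", "W", "p_value"])
    return {"edges": edges, "genes": genes, "missing": pd.DataFrame({"gene_id": missing})}
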