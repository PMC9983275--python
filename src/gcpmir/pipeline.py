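"""End-to-end orchestration of the module-discovery analysis.

Stages: simulate -> differential expression per RNA class -> correlation +
evidence network -> topology + SVM-RFE -> RNs prioritization -> module
extraction -> Cox risk stratification + clinical associations -> exhaustive
subset SVM classification. Each stage is also callable standalone; the
pipeline wires them with one seed and writes a manifest so a bundle can be
reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from gcpmir import io as gio
from gcpmir.classify import search_combinations, split_cohort
from gcpmir.de import normalize_counts, test_differential
from gcpmir.module import extract_module, validate_module
from gcpmir.network import NetworkThresholds, build_network, compute_topology, spearman_edges
from gcpmir.rns import log2_zscore, rns_scores, svm_rfe_rank, top_genes
from gcpmir.simulate import (
    ExpressionCohort,
    GroundTruth,
    InteractionEvidence,
    SimulationConfig,
    generate_cohort,
    generate_evidence,
)
from gcpmir.survival import chi_square_association, fit_cox, risk_stratify

__all__ = ["PipelineConfig", "run_pipeline", "planted_edge_f1"]


@dataclass
class PipelineConfig:
    """Configuration for a full synthetic run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    alpha: float = 0.05
    de_method: str = "nbwald"
    thresholds: NetworkThresholds = field(default_factory=NetworkThresholds)
    cerna_closure: bool = True
    top_k: int = 10
    exclude: List[str] = field(default_factory=list)
    split_ratio: float = 0.7
    split_seed: int = 17
    cutoff_rule: str = "median"
    svm_kernel: str = "linear"
    svm_C: float = 1.0
    classifier_panel_size: int = 14
    max_subset_size: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 < self.split_ratio < 1.0:
            raise ValueError("split_ratio must be in (0, 1)")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


def planted_edge_f1(net, truth: GroundTruth) -> Dict[str, float]:
    """Precision/recall/F1 of recovered edges against the planted edge list."""
    recovered = {frozenset(e) for e in net.edges}
    planted = {frozenset((m, t)) for m, t, _ in truth.planted_edges}
    tp = len(recovered & planted)
    prec = tp / len(recovered) if recovered else 0.0
    rec = tp / len(planted) if planted else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
    return {"precision": prec, "recall": rec, "f1": f1, "n_recovered": len(recovered)}


def run_pipeline(config: PipelineConfig, outdir: Optional[str | Path] = None) -> Dict:
    """Execute the full analysis on a synthetic cohort.

    Returns a result bundle (dict). If the network filters leave no nodes,
    downstream stages are skipped and the bundle status is
    ``"empty_network"``; partial outputs are retained.
    """
    bundle: Dict = {"status": "ok", "stages": {}}

    cohort, truth = generate_cohort(config.simulation)
    evidence = generate_evidence(truth, config.simulation)
    bundle["cohort"], bundle["truth"], bundle["evidence"] = cohort, truth, evidence
    bundle["stages"]["simulate"] = "ok"

    # differential expression, per RNA class (BH within class)
    norm: Dict[str, pd.DataFrame] = {}
    de: Dict[str, pd.DataFrame] = {}
    for cls in ("miRNA", "mRNA", "lncRNA"):
        norm[cls] = normalize_counts(cohort.counts(cls), pseudo_reference=True)
        de[cls] = test_differential(
            norm[cls], cohort.group, alpha=config.alpha, method=config.de_method, rna_class=cls
        )
    bundle["normalized"], bundle["de"] = norm, de
    bundle["stages"]["de"] = "ok"

    sig = {cls: de[cls].loc[de[cls]["significant"], "gene_id"].tolist() for cls in de}
    corr_frames = []
    if sig["miRNA"]:
        for cls in ("mRNA", "lncRNA"):
            if sig[cls]:
                corr_frames.append(
                    spearman_edges(
                        norm["miRNA"].loc[sig["miRNA"]],
                        norm[cls].loc[sig[cls]],
                        cls,
                        p_max=config.thresholds.corr_p_max,
                    )
                )
    corr_edges = (
        pd.concat(corr_frames, ignore_index=True)
        if corr_frames
        else pd.DataFrame(columns=["mirna_id", "partner_id", "partner_class", "scc", "p_value"])
    )
    bundle["corr_edges"] = corr_edges

    direction = pd.concat(
        [d.loc[d["significant"]].set_index("gene_id")["direction"] for d in de.values()]
    )
    net = build_network(
        direction,
        corr_edges,
        evidence.mrna,
        evidence.lncrna,
        thresholds=config.thresholds,
        cerna_closure=config.cerna_closure,
    )
    bundle["network"] = net
    bundle["edge_recovery"] = planted_edge_f1(net, truth)
    if net.graph["status"] == "empty_network" or net.number_of_nodes() < 2:
        bundle["status"] = "empty_network"
        bundle["stages"]["network"] = "empty_network"
        if outdir is not None:
            _write_bundle(bundle, config, Path(outdir))
        return bundle
    bundle["stages"]["network"] = "ok"

    # topology + SVM-RFE -> RNs prioritization
    topology = compute_topology(net)
    net_genes = [n for n in net.nodes if not topology.loc[n, "excluded"]]
    expr_net = pd.concat(
        [norm[cls].loc[[g for g in net_genes if g in norm[cls].index]] for cls in norm]
    )
    expr_net = expr_net.loc[[g for g in net_genes if g in expr_net.index]]
    ranking = svm_rfe_rank(expr_net, cohort.group.to_numpy(), C=config.svm_C)
    rns_table = rns_scores(topology, ranking)
    selected = top_genes(rns_table, min(config.top_k, len(rns_table)), exclude=config.exclude)
    bundle["topology"], bundle["ranking"], bundle["rns_table"] = topology, ranking, rns_table
    bundle["selected"] = selected
    bundle["stages"]["rns"] = "ok"

    # module extraction: selected miRNAs (with a known family) + lncRNAs
    klass = {n: net.nodes[n]["klass"] for n in net.nodes}
    anchors = [
        g
        for g in selected
        if (klass[g] == "miRNA" and g in truth.family_map) or klass[g] == "lncRNA"
    ]
    fams_selected = {truth.family_map[g] for g in anchors if g in truth.family_map}
    if len(fams_selected) < 2:
        bundle["status"] = "no_module"
        bundle["stages"]["module"] = "no_module"
        if outdir is not None:
            _write_bundle(bundle, config, Path(outdir))
        return bundle
    fam_map = {g: f for g, f in truth.family_map.items() if f in fams_selected}
    module = extract_module(net, anchors, fam_map)
    bundle["module"] = module
    bundle["stages"]["module"] = "ok"

    # 7:3 split used for survival training and classifier evaluation
    train_ids, test_ids = split_cohort(
        cohort.sample_ids, ratio=config.split_ratio, seed=config.split_seed
    )
    bundle["split"] = {"train": train_ids, "test": test_ids}

    # survival on module miRNAs
    module_mirnas = list(module.mirnas)
    surv = cohort.annotations
    model = fit_cox(
        norm["miRNA"].loc[module_mirnas, train_ids],
        surv.loc[train_ids],
        module_mirnas,
        cutoff_rule=config.cutoff_rule,
    )
    strat = {
        name: risk_stratify(model, norm["miRNA"].loc[module_mirnas, ids], surv.loc[ids])
        for name, ids in (
            ("train", train_ids),
            ("test", test_ids),
            ("whole", cohort.sample_ids),
        )
    }
    bundle["risk_model"], bundle["stratification"] = model, strat
    bundle["stages"]["survival"] = "ok"

    # clinical association tables for module miRNAs and lncRNAs
    assoc_rows = []
    clinical_cols = [c for c in surv.columns if c not in ("group", "survival_time", "event")]
    for g in module_mirnas + list(module.lncrnas):
        cls = klass[g]
        expr_g = norm["miRNA" if cls == "miRNA" else "lncRNA"].loc[g]
        for cat in clinical_cols:
            _, stat, p = chi_square_association(expr_g, surv[cat])
            assoc_rows.append((g, cat, stat, p))
    associations = pd.DataFrame(
        assoc_rows, columns=["gene_id", "characteristic", "chi_square", "p_value"]
    )
    bundle["associations"] = associations
    bundle["stages"]["associations"] = "ok"

    # module-level validation on the held-out samples
    expr_all = pd.concat([log2_zscore(norm[cls]) for cls in norm])
    contrast = {"ESGC_vs_LSGC": surv.loc[test_ids, "group"]}
    bundle["validation"] = validate_module(module, expr_all.loc[:, test_ids], contrast)
    bundle["stages"]["validate"] = "ok"

    # exhaustive subset SVM on the module gene panel
    panel = (module_mirnas + list(module.lncrnas) + list(module.mrnas))[
        : config.classifier_panel_size
    ]
    labels_tr = surv.loc[train_ids, "group"].to_numpy()
    labels_te = surv.loc[test_ids, "group"].to_numpy()
    expr_panel = expr_all.loc[panel]
    subset_results = search_combinations(
        expr_panel.loc[:, train_ids],
        labels_tr,
        expr_panel.loc[:, test_ids],
        labels_te,
        kernel=config.svm_kernel,
        C=config.svm_C,
        max_size=config.max_subset_size,
    )
    bundle["subset_results"] = subset_results
    bundle["best_subset"] = {
        "genes": list(subset_results.iloc[0]["genes"]),
        "auc": float(subset_results.iloc[0]["auc"]),
    }
    bundle["stages"]["classify"] = "ok"

    if outdir is not None:
        _write_bundle(bundle, config, Path(outdir))
    return bundle


def _write_bundle(bundle: Dict, config: PipelineConfig, outdir: Path) -> None:
    """Persist every stage output plus a manifest with file hashes."""
    outdir.mkdir(parents=True, exist_ok=True)
    cohort: ExpressionCohort = bundle["cohort"]
    gio.write_expression(cohort.counts_mirna, outdir / "counts_mirna.tsv")
    gio.write_expression(cohort.counts_mrna, outdir / "counts_mrna.tsv")
    gio.write_expression(cohort.counts_lncrna, outdir / "counts_lncrna.tsv")
    cohort.annotations.to_csv(outdir / "annotations.tsv", sep="\t")
    ev: InteractionEvidence = bundle["evidence"]
    gio.write_tsv(ev.mrna, outdir / "evidence_mrna.tsv")
    gio.write_tsv(ev.lncrna, outdir / "evidence_lncrna.tsv")
    gio.write_json(bundle["truth"], outdir / "truth.json")
    for cls, d in bundle.get("de", {}).items():
        gio.write_tsv(d, outdir / f"de_{cls.lower()}.tsv")
    if "corr_edges" in bundle:
        gio.write_tsv(bundle["corr_edges"], outdir / "correlation_edges.tsv")
    net = bundle.get("network")
    if net is not None and net.number_of_nodes() > 0:
        gio.write_graphml(net, outdir / "network.graphml")
        edge_rows = [
            {"mirna_id": u, "partner_id": v, **d} for u, v, d in net.edges(data=True)
        ]
        gio.write_tsv(pd.DataFrame(edge_rows), outdir / "network_edges.tsv")
    if "topology" in bundle:
        gio.write_tsv(bundle["topology"].reset_index(), outdir / "topology.tsv")
    if "rns_table" in bundle:
        gio.write_tsv(bundle["rns_table"].round(3).reset_index(), outdir / "rns_table.tsv")
    if "module" in bundle:
        gio.write_json(bundle["module"], outdir / "module.json")
    if "risk_model" in bundle:
        gio.write_json(bundle["risk_model"], outdir / "risk_model.json")
    if "stratification" in bundle:
        for name, s in bundle["stratification"].items():
            gio.write_tsv(s.km_curves, outdir / f"km_{name}.tsv")
        scores = pd.DataFrame(
            {
                "risk_score": bundle["stratification"]["whole"].scores,
                "risk_group": bundle["stratification"]["whole"].groups,
            }
        )
        scores.index.name = "sample_id"
        scores.to_csv(outdir / "risk_scores.tsv", sep="\t")
    if "associations" in bundle:
        gio.write_tsv(bundle["associations"], outdir / "associations.tsv")
    if "subset_results" in bundle:
        top = bundle["subset_results"].head(200).copy()
        top["genes"] = top["genes"].map(lambda t: ",".join(t))
        gio.write_tsv(top, outdir / "subset_auc_top200.tsv")
    manifest = {
        "config": gio.to_jsonable(config),
        "status": bundle["status"],
        "stages": bundle["stages"],
        "edge_recovery": bundle.get("edge_recovery"),
        "files": {
            p.name: gio.sha256_file(p)
            for p in sorted(outdir.iterdir())
            if p.name != "manifest.json" and p.is_file()
        },
    }
    gio.write_json(manifest, outdir / "manifest.json")
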