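"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from gcpmir.pipeline import PipelineConfig, run_pipeline
from gcpmir.simulate import FamilySpec, ModuleSpec, SimulationConfig

warnings.filterwarnings("ignore", category=UserWarning)


def make_null_module(
    n_members: int = 1,
    n_targets: int = 2,
    n_lnc_targets: int = 0,
    rho_plant: float = 0.0,
    rho_family: float = 0.0,
    effect: float = 0.0,
) -> ModuleSpec:
    """One-family module spec with configurable coupling/effects; the
    default is fully null (no effects, no dependence)."""
    return ModuleSpec(
        families=[
            FamilySpec("fam", [f"m{i}" for i in range(1, n_members + 1)], rho_family)
        ],
        shared_mrna_targets=[f"t{i}" for i in range(1, n_targets + 1)],
        shared_lncrna_targets=[f"lt{i}" for i in range(1, n_lnc_targets + 1)],
        mirna_log2fc=-effect,
        target_log2fc=effect,
        rho_plant=rho_plant,
    )


def make_config(module: ModuleSpec, n_per_group: int = 100, seed: int = 0, **kw) -> SimulationConfig:
    defaults = dict(
        n_early=n_per_group,
        n_late=n_per_group,
        n_mirna=max(10, len(module.mirnas) + 2),
        n_mrna=max(20, len(module.shared_mrna_targets) + 5),
        n_lncrna=max(4, len(module.shared_lncrna_targets) + 2),
        extra_de_mirna=0,
        extra_de_mrna=0,
        extra_de_lncrna=0,
        clinical=[],
        seed=seed,
    )
    defaults.update(kw)
    return SimulationConfig(module=module, **defaults)


@pytest.fixture(scope="session")
def pipeline_bundle():
    """A reduced but complete synthetic pipeline run shared across tests."""
    cfg = PipelineConfig(
        simulation=SimulationConfig(
            n_early=80, n_late=80, n_mirna=40, n_mrna=150, n_lncrna=15, seed=42
        ),
        classifier_panel_size=10,
    )
    return run_pipeline(cfg)


# ---------------------------------------------------------------------------
# independent oracles


def spearman_sum_d2(x, y) -> float:
    """Definitional Spearman for tie-free data: 1 - 6*sum(d^2)/(n(n^2-1))."""
    xr = pd.Series(x).rank().to_numpy()
    yr = pd.Series(y).rank().to_numpy()
    d2 = np.sum((xr - yr) ** 2)
    n = len(xr)
    return 1.0 - 6.0 * d2 / (n * (n**2 - 1))


def pairwise_auc(scores, labels) -> float:
    """Brute-force AUC over all positive-negative pairs (ties count 1/2)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_topology(g: nx.Graph) -> pd.DataFrame:
    """All-pairs BFS plus explicit shortest-path enumeration.

    Independent of the implementation under test: distances by hand-rolled
    BFS, betweenness by recursively enumerating every shortest path of
    every pair and counting interior visits, normalized per component by
    (nc-1)(nc-2)/2.
    """
    nodes = list(g.nodes)
    dist: dict = {}
    for s in nodes:
        d = {s: 0}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for w in g.neighbors(u):
                    if w not in d:
                        d[w] = d[u] + 1
                        nxt.append(w)
            frontier = nxt
        dist[s] = d

    def shortest_paths(s, t):
        d = dist[s]

        def rec(u):
            if u == s:
                return [[s]]
            return [
                path + [u]
                for w in g.neighbors(u)
                if w in d and d[w] == d[u] - 1
                for path in rec(w)
            ]

        return rec(t)

    comp_of = {}
    comps = []
    for s in nodes:
        if s not in comp_of:
            members = set(dist[s])
            comps.append(members)
            for m in members:
                comp_of[m] = len(comps) - 1

    through = {v: 0.0 for v in nodes}
    for ci, members in enumerate(comps):
        ms = sorted(members, key=str)
        for i, s in enumerate(ms):
            for t in ms[i + 1 :]:
                paths = shortest_paths(s, t)
                sigma = len(paths)
                for v in set(p for path in paths for p in path[1:-1]):
                    cnt = sum(v in path[1:-1] for path in paths)
                    through[v] += cnt / sigma

    rows = []
    for v in nodes:
        members = comps[comp_of[v]]
        nc = len(members)
        if nc == 1:
            rows.append((v, g.degree(v), np.nan, np.nan, np.nan))
            continue
        L = sum(dist[v][u] for u in members)
        denom = (nc - 1) * (nc - 2) / 2.0
        B = through[v] / denom if denom > 0 else 0.0
        rows.append((v, g.degree(v), L, (nc - 1) / L, B))
    return pd.DataFrame(rows, columns=["node_id", "D", "L", "C", "B"]).set_index(
        "node_id"
    )
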