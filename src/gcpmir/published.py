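"""Published statistics from the gastric-cancer progression study.

These are the printed inputs the package checks itself against: the top-ten
prioritization table (degree D, normalized betweenness B, closeness C and
RNs score in a 155-node network), the seven-miRNA risk-score coefficients
with the training-cohort median cutoff, the cohort sizes, and one printed
clinical contingency table. Total shortest-path length L and the SVM-RFE
rank score Rs are not printed directly; :func:`invert_rns_row` recovers
them from the closeness convention C = (N - 1)/L and RNs = D * Rs / L.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
import pandas as pd

__all__ = [
    "NETWORK_N_NODES",
    "TOP_TEN",
    "RISK_COEFFICIENTS",
    "RISK_CUTOFF_MEDIAN",
    "COHORT_SIZES",
    "MIR182_AGE_TABLE",
    "FAMILY_MAP",
    "invert_rns_row",
    "recover_table_integers",
]

#: nodes in the published progression network (22 miRNA + 126 mRNA + 7 lncRNA)
NETWORK_N_NODES = 155

#: top-ten genes by RNs score: degree, normalized betweenness, closeness, RNs
TOP_TEN = pd.DataFrame(
    [
        ("miR-203a-3p", 25, 0.175, 0.394, 9.847, "miR-203"),
        ("miR-200c-3p", 24, 0.063, 0.386, 8.421, "miR-200"),
        ("miR-200a-3p", 25, 0.083, 0.394, 7.609, "miR-200"),
        ("miR-141-3p", 28, 0.110, 0.400, 7.127, "miR-200"),
        ("miR-200b-3p", 23, 0.058, 0.390, 6.522, "miR-200"),
        ("miR-182-5p", 17, 0.083, 0.378, 6.140, "miR-183"),
        ("miR-429", 28, 0.098, 0.400, 5.091, "miR-200"),
        ("miR-183-5p", 15, 0.063, 0.361, 4.426, "miR-183"),
        ("H19", 13, 0.145, 0.428, 5.561, "lncRNA"),
        ("CLLU1", 17, 0.195, 0.453, 5.500, "lncRNA"),
    ],
    columns=["name", "D", "B", "C", "RNs", "family"],
).set_index("name")

#: multivariable Cox coefficients of the seven-miRNA risk score
RISK_COEFFICIENTS = {
    "miR-200b-3p": 0.0316,
    "miR-141-3p": 0.0716,
    "miR-200c-3p": -0.0193,
    "miR-200a-3p": -0.1105,
    "miR-429": 0.1529,
    "miR-182-5p": -0.5501,
    "miR-183-5p": 0.3274,
}

#: training-cohort median risk score used as the high/low cutoff
RISK_CUTOFF_MEDIAN = -2.4568

#: (total, early-stage, late-stage) and the 7:3 train/test sizes
COHORT_SIZES = {"total": 257, "early": 129, "late": 128, "train": 180, "test": 77}

#: miR-182-5p high/low x age (<=60 / >60) contingency table, reported p = 0.004
MIR182_AGE_TABLE = [[36, 53], [101, 67]]

#: family assignment of the seven module miRNAs
FAMILY_MAP = {
    "miR-200a-3p": "miR-200",
    "miR-200b-3p": "miR-200",
    "miR-200c-3p": "miR-200",
    "miR-141-3p": "miR-200",
    "miR-429": "miR-200",
    "miR-182-5p": "miR-183",
    "miR-183-5p": "miR-183",
}


def invert_rns_row(
    D: int, C: float, RNs: float, n_nodes: int = NETWORK_N_NODES, tol: float = 0.2
) -> Tuple[int, int]:
    """Recover the integer (L, Rs) behind one printed table row.

    Enumerates integer L for which (n_nodes - 1)/L rounds to the printed
    closeness at 3 decimals, solves Rs = RNs * L / D for each candidate and
    keeps the L whose Rs is nearest an integer (residual must be < ``tol``).
    This is the independent oracle for the score identity RNs = D * Rs / L.
    """
    n1 = n_nodes - 1
    lo = int(np.floor(n1 / (C + 5e-4)))
    hi = int(np.ceil(n1 / max(C - 5e-4, 1e-9)))
    best = None
    for L in range(max(lo, n1), hi + 1):
        if round(n1 / L, 3) != round(C, 3):
            continue
        rs = RNs * L / D
        resid = abs(rs - round(rs))
        if resid < tol and (best is None or resid < best[2]):
            best = (L, int(round(rs)), resid)
    if best is None:
        raise ValueError(
            f"no integer (L, Rs) consistent with D={D}, C={C}, RNs={RNs}"
        )
    return best[0], best[1]


def recover_table_integers(
    table: pd.DataFrame = TOP_TEN, n_nodes: int = NETWORK_N_NODES
) -> pd.DataFrame:
    """Apply :func:`invert_rns_row` to every printed row, returning the
    recovered L and Rs alongside the forward-recomputed RNs."""
    rows = []
    for name, r in table.iterrows():
        L, rs = invert_rns_row(int(r["D"]), float(r["C"]), float(r["RNs"]), n_nodes)
        rows.append((name, int(r["D"]), L, rs, round(int(r["D"]) * rs / L, 3)))
    return pd.DataFrame(
        rows, columns=["name", "D", "L", "Rs", "RNs_recomputed"]
    ).set_index("name")
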