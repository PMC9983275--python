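"""Exhaustive gene-subset SVM search for stage classification.

Every non-empty subset of a candidate gene panel is used to train a linear
SVM on the training cohort (features standardized on training statistics);
test-cohort decision values feed the ROC, and the AUC is computed by the
Mann-Whitney identity (ties contribute 1/2). Subsets are ranked by AUC,
ties broken toward smaller subsets then lexicographically.
"""

from __future__ import annotations

from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.svm import SVC

__all__ = ["split_cohort", "mannwhitney_auc", "roc_auc", "search_combinations"]


def split_cohort(
    sample_ids: Sequence[str], ratio: float = 0.7, seed: int = 0
) -> Tuple[List[str], List[str]]:
    """Seeded random partition into train/test of sizes
    (round(ratio*n), n - round(ratio*n))."""
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    ids = list(sample_ids)
    if len(ids) < 2:
        raise ValueError("need >= 2 samples to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = int(round(ratio * len(ids)))
    train = sorted(ids[i] for i in perm[:n_train])
    test = sorted(ids[i] for i in perm[n_train:])
    return train, test


def mannwhitney_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC as the Mann-Whitney U statistic over positive-negative pairs,
    divided by n1*n0; tied scores contribute 1/2."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = s[y == 1]
    neg = s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> Dict[str, object]:
    """ROC points plus the Mann-Whitney AUC.

    The stored ROC starts at (0, 0) and ends at (1, 1); its trapezoidal
    area equals the Mann-Whitney AUC (checked in the test suite as a dual
    route).
    """
    y = np.asarray(labels)
    if len(np.unique(y)) != 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thr = roc_curve(y, np.asarray(scores, dtype=float))
    return {
        "fpr": fpr,
        "tpr": tpr,
        "thresholds": thr,
        "auc": mannwhitney_auc(scores, labels),
    }


def _standardize(train: np.ndarray, other: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0.0] = 1.0
    return (train - mu) / sd, (other - mu) / sd


def search_combinations(
    train_expr: pd.DataFrame,
    train_labels: Sequence[str],
    test_expr: pd.DataFrame,
    test_labels: Sequence[str],
    genes: Optional[Sequence[str]] = None,
    kernel: str = "linear",
    C: float = 1.0,
    max_size: Optional[int] = None,
    positive_label: str = "LSGC",
) -> pd.DataFrame:
    """Train/evaluate an SVM for every non-empty gene subset.

    Expression matrices are genes x samples on a comparable scale (e.g.
    log2-transformed normalized counts); features are standardized with
    training statistics inside each fit. Returns one row per subset with
    its AUC, ranked descending (ties -> smaller subset, then lexicographic
    gene tuple).
    """
    genes = list(genes) if genes is not None else list(train_expr.index)
    if len(genes) > 20:
        raise ValueError("exhaustive search is capped at 20 genes")
    for g in genes:
        if g not in train_expr.index or g not in test_expr.index:
            raise ValueError(f"gene {g!r} missing from a cohort")
    y_tr = (np.asarray(train_labels) == positive_label).astype(int)
    y_te = (np.asarray(test_labels) == positive_label).astype(int)
    if len(np.unique(y_tr)) != 2 or len(np.unique(y_te)) != 2:
        raise ValueError("both classes must be present in train and test")
    Xtr_all = train_expr.loc[genes].to_numpy(dtype=float).T
    Xte_all = test_expr.loc[genes].to_numpy(dtype=float).T
    max_size = max_size or len(genes)
    rows = []
    for k in range(1, max_size + 1):
        for subset in combinations(range(len(genes)), k):
            Xtr, Xte = _standardize(Xtr_all[:, subset], Xte_all[:, subset])
            clf = SVC(kernel=kernel, C=C)
            clf.fit(Xtr, y_tr)
            auc = mannwhitney_auc(clf.decision_function(Xte), y_te)
            rows.append((tuple(genes[i] for i in subset), k, auc))
    out = pd.DataFrame(rows, columns=["genes", "n_genes", "auc"])
    out = out.sort_values(
        by=["auc", "n_genes", "genes"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
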