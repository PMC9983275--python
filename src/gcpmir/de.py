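"""Differential-expression screen between early- and late-stage groups.

Counts-in / DEG-list-out. Library-size normalization follows the
median-of-ratios convention; the default test is a negative-binomial Wald
test with method-of-moments dispersion, with a Wilcoxon rank-sum
alternative. Benjamini-Hochberg adjustment is applied within one RNA class
at a time (callers screen each class separately).
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["size_factors", "normalize_counts", "test_differential"]


def size_factors(counts: pd.DataFrame, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors.

    Each sample's factor is the median, over reference genes, of the ratio
    of its count to the gene's geometric mean across samples. Genes with a
    zero in any sample drop out of the reference; if none survive, set
    ``pseudo_reference=True`` to add a pseudo-count of 1 when forming the
    reference.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    x = counts.to_numpy(dtype=float)
    if pseudo_reference:
        x = x + 1.0
    with np.errstate(divide="ignore"):
        logx = np.log(x)
    finite = np.isfinite(logx).all(axis=1)
    if not finite.any():
        raise ValueError(
            "no gene has positive counts in every sample; "
            "re-run with pseudo_reference=True"
        )
    log_gm = logx[finite].mean(axis=1, keepdims=True)
    ratios = logx[finite] - log_gm
    sf = np.exp(np.median(ratios, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame, pseudo_reference: bool = False) -> pd.DataFrame:
    """Divide each sample column by its median-of-ratios size factor."""
    sf = size_factors(counts, pseudo_reference=pseudo_reference)
    return counts / sf


def _nb_wald(
    norm: np.ndarray, early: np.ndarray, late: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Wald test on log mean difference of NB counts.

    Per-gene dispersion alpha is estimated by pooled method of moments,
    Var(x) = mu + alpha*mu^2, from the within-group spread; the variance of
    each group's log mean follows by the delta method. The reference
    distribution is t with n-2 df, which keeps the null near nominal at
    moderate group sizes.
    """
    n0, n1 = early.shape[1], late.shape[1]
    mu0 = early.mean(axis=1)
    mu1 = late.mean(axis=1)
    v0 = early.var(axis=1, ddof=1)
    v1 = late.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        a0 = (v0 - mu0) / np.square(mu0)
        a1 = (v1 - mu1) / np.square(mu1)
    alpha = np.nanmean(np.stack([a0, a1]), axis=0)
    alpha = np.clip(np.nan_to_num(alpha, nan=0.0), 0.0, None)
    m0 = mu0 + 0.5
    m1 = mu1 + 0.5
    var_log = (1.0 / m0 + alpha) / n0 + (1.0 / m1 + alpha) / n1
    z = (np.log(m1) - np.log(m0)) / np.sqrt(var_log)
    p = 2.0 * stats.t.sf(np.abs(z), df=n0 + n1 - 2)
    return z, p


def _wilcoxon(early: np.ndarray, late: np.ndarray) -> np.ndarray:
    """Two-sided rank-sum p per gene; constant genes get p = 1."""
    p = np.ones(early.shape[0])
    for i in range(early.shape[0]):
        a, b = late[i], early[i]
        if np.ptp(np.concatenate([a, b])) == 0.0:
            continue
        p[i] = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
    return p


def test_differential(
    norm_counts: pd.DataFrame,
    group_labels: pd.Series,
    alpha: float = 0.05,
    method: str = "nbwald",
    rna_class: Optional[str] = None,
) -> pd.DataFrame:
    """Per-gene stage contrast (LSGC vs ESGC) on normalized counts.

    Returns a table with ``log2_fold_change``, ``p_value``, ``adjusted_p``
    (Benjamini-Hochberg within the supplied gene set), ``direction`` and a
    ``significant`` flag (``adjusted_p < alpha``).
    """
    groups = pd.Series(group_labels).reindex(norm_counts.columns)
    if groups.isna().any():
        raise ValueError("group label missing for some samples")
    levels = sorted(groups.unique())
    if set(levels) != {"ESGC", "LSGC"}:
        raise ValueError(f"expected groups ESGC/LSGC, got {levels}")
    early = norm_counts.loc[:, groups == "ESGC"].to_numpy(dtype=float)
    late = norm_counts.loc[:, groups == "LSGC"].to_numpy(dtype=float)
    if early.shape[1] < 2 or late.shape[1] < 2:
        raise ValueError("each group needs >= 2 samples")

    lfc = np.log2((late.mean(axis=1) + 0.5) / (early.mean(axis=1) + 0.5))
    if method == "nbwald":
        _, p = _nb_wald(norm_counts.to_numpy(dtype=float), early, late)
    elif method == "wilcoxon":
        p = _wilcoxon(early, late)
    else:
        raise ValueError(f"unknown method {method!r}")
    p = np.clip(np.nan_to_num(p, nan=1.0), 0.0, 1.0)
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    out = pd.DataFrame(
        {
            "gene_id": norm_counts.index,
            "log2_fold_change": lfc,
            "p_value": p,
            "adjusted_p": np.maximum(adj, p),
            "direction": np.where(lfc > 0, "up", "down"),
            "significant": adj < alpha,
        }
    )
    if rna_class is not None:
        out.insert(1, "rna_class", rna_class)
    return out.reset_index(drop=True)
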