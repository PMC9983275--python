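"""Cox risk modeling, risk-group stratification and clinical associations.

A multivariable Cox proportional-hazards model (Efron ties, via lifelines)
is fitted on module-miRNA expression transformed to log2(normalized count
+ 1) and z-scored on the training cohort. The linear predictor is the risk
score; patients above the training-cohort cutoff (median by default) form
the high-risk group. Survival separation is tested with the two-group
log-rank test on Kaplan-Meier estimates. Clinicopathological association
uses a Pearson chi-square on the r x 2 table of category level x high/low
gene expression (median split), with Yates continuity correction for the
2 x 2 case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

__all__ = [
    "RiskModel",
    "StratificationResult",
    "transform_expression",
    "fit_cox",
    "risk_stratify",
    "chi_square_table",
    "chi_square_association",
]


@dataclass
class RiskModel:
    """Fitted risk score: genes, log-hazard coefficients, and the scale on
    which expression must be supplied for scoring to be reproducible."""

    genes: List[str]
    coefficients: Dict[str, float]
    hazard_ratios: Dict[str, float]
    ci_lower: Dict[str, float]
    ci_upper: Dict[str, float]
    cutoff: float
    scale: Dict[str, Tuple[float, float]]  # gene -> (mean, sd) of log2(x+1)
    cutoff_rule: str = "median"

    def __post_init__(self) -> None:
        if set(self.genes) != set(self.coefficients):
            raise ValueError("genes and coefficients disagree")
        if not np.isfinite(self.cutoff):
            raise ValueError("cutoff must be finite")

    def score(self, expr_counts: pd.DataFrame) -> pd.Series:
        """Risk score = sum_i beta_i * x_i on the model's expression scale."""
        missing = [g for g in self.genes if g not in expr_counts.index]
        if missing:
            raise ValueError(f"genes missing from expression matrix: {missing}")
        x = transform_expression(expr_counts.loc[self.genes], self.scale)
        beta = np.array([self.coefficients[g] for g in self.genes])
        return pd.Series(beta @ x.to_numpy(), index=expr_counts.columns, name="risk_score")


@dataclass
class StratificationResult:
    scores: pd.Series
    groups: pd.Series  # "high" / "low"
    km_curves: pd.DataFrame  # columns: group, time, survival, at_risk
    logrank_statistic: float
    logrank_p: float


def transform_expression(
    expr_counts: pd.DataFrame,
    scale: Optional[Dict[str, Tuple[float, float]]] = None,
) -> pd.DataFrame:
    """log2(x + 1), then per-gene z-scoring.

    With ``scale`` given (gene -> (mean, sd) learned on training data) the
    stored parameters are applied; otherwise they are estimated from the
    supplied matrix.
    """
    x = np.log2(expr_counts.to_numpy(dtype=float) + 1.0)
    out = pd.DataFrame(x, index=expr_counts.index, columns=expr_counts.columns)
    if scale is None:
        mu = out.mean(axis=1)
        sd = out.std(axis=1, ddof=0).replace(0.0, 1.0)
    else:
        mu = pd.Series({g: scale[g][0] for g in out.index})
        sd = pd.Series({g: scale[g][1] for g in out.index}).replace(0.0, 1.0)
    return out.sub(mu, axis=0).div(sd, axis=0)


def fit_cox(
    expr_counts: pd.DataFrame,
    survival: pd.DataFrame,
    genes: Sequence[str],
    cutoff_rule: Union[str, float] = "median",
) -> RiskModel:
    """Fit the multivariable Cox model on training expression.

    ``survival`` must carry ``survival_time`` and ``event`` indexed by
    sample; ``expr_counts`` is genes x samples of (normalized) counts.
    Zero-variance genes are dropped with a warning; fewer than 10 observed
    events is an error. ``cutoff_rule``: "median" (default), "mean", or an
    explicit numeric cutoff.
    """
    missing = [g for g in genes if g not in expr_counts.index]
    if missing:
        raise ValueError(f"genes missing from expression matrix: {missing}")
    surv = survival.loc[expr_counts.columns]
    if int(surv["event"].sum()) < 10:
        raise ValueError("need >= 10 observed events to fit the model")
    sub = expr_counts.loc[list(genes)]
    keep = []
    for g in genes:
        if np.ptp(sub.loc[g].to_numpy(dtype=float)) == 0.0:
            warnings.warn(f"zero-variance gene dropped from Cox model: {g}")
        else:
            keep.append(g)
    if not keep:
        raise ValueError("all candidate genes are constant")
    logx = np.log2(sub.loc[keep].to_numpy(dtype=float) + 1.0)
    scale = {
        g: (float(logx[i].mean()), float(logx[i].std()))
        for i, g in enumerate(keep)
    }
    X = transform_expression(sub.loc[keep], scale)
    df = X.T.copy()
    df["survival_time"] = surv["survival_time"].to_numpy(dtype=float)
    df["event"] = surv["event"].to_numpy(dtype=int)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="survival_time", event_col="event")
    beta = cph.params_.to_dict()
    summary = cph.summary
    model = RiskModel(
        genes=list(keep),
        coefficients={g: float(beta[g]) for g in keep},
        hazard_ratios={g: float(np.exp(beta[g])) for g in keep},
        ci_lower={g: float(summary.loc[g, "coef lower 95%"]) for g in keep},
        ci_upper={g: float(summary.loc[g, "coef upper 95%"]) for g in keep},
        cutoff=0.0,
        scale=scale,
    )
    scores = model.score(expr_counts)
    if cutoff_rule == "median":
        model.cutoff = float(scores.median())
    elif cutoff_rule == "mean":
        model.cutoff = float(scores.mean())
    else:
        model.cutoff = float(cutoff_rule)
    model.cutoff_rule = str(cutoff_rule)
    return model


def _km_curve(time: np.ndarray, event: np.ndarray, label: str) -> pd.DataFrame:
    km = KaplanMeierFitter()
    km.fit(time, event_observed=event, label=label)
    sf = km.survival_function_
    at_risk = km.event_table["at_risk"].reindex(sf.index).ffill()
    return pd.DataFrame(
        {
            "group": label,
            "time": sf.index.to_numpy(dtype=float),
            "survival": sf[label].to_numpy(dtype=float),
            "at_risk": at_risk.to_numpy(dtype=float),
        }
    )


def risk_stratify(
    model: RiskModel, expr_counts: pd.DataFrame, survival: pd.DataFrame
) -> StratificationResult:
    """Score a cohort, split at the model cutoff, and compare survival.

    High-risk iff score > cutoff. Returns per-patient scores and groups,
    Kaplan-Meier curves per group, and the 1-df two-group log-rank test.
    """
    scores = model.score(expr_counts)
    groups = pd.Series(
        np.where(scores > model.cutoff, "high", "low"), index=scores.index, name="risk_group"
    )
    surv = survival.loc[scores.index]
    t = surv["survival_time"].to_numpy(dtype=float)
    e = surv["event"].to_numpy(dtype=int)
    hi = (groups == "high").to_numpy()
    curves = []
    for label, mask in (("high", hi), ("low", ~hi)):
        if mask.any():
            curves.append(_km_curve(t[mask], e[mask], label))
    km_curves = pd.concat(curves, ignore_index=True) if curves else pd.DataFrame()
    if hi.any() and (~hi).any():
        res = logrank_test(t[hi], t[~hi], event_observed_A=e[hi], event_observed_B=e[~hi])
        stat, p = float(res.test_statistic), float(res.p_value)
    else:
        stat, p = np.nan, np.nan
    return StratificationResult(scores, groups, km_curves, stat, p)


def chi_square_table(table) -> Tuple[float, float]:
    """Pearson chi-square on an r x c contingency table: Yates continuity
    correction for the 2 x 2 case, uncorrected otherwise. Warns when any
    expected cell drops below 1 (an exact test would be preferable there)."""
    arr = np.asarray(table, dtype=float)
    stat, p, _, expected = stats.chi2_contingency(
        arr, correction=(arr.shape == (2, 2))
    )
    if (expected < 1.0).any():
        warnings.warn("expected cell count < 1; consider an exact test")
    return float(stat), float(p)


def chi_square_association(
    gene_expr: pd.Series,
    clinical_category: pd.Series,
    dichotomize: str = "median",
) -> Tuple[pd.DataFrame, float, float]:
    """Association between a gene's high/low expression and a clinical
    category.

    Expression is median-split into High/Low; the r x 2 contingency table
    is tested with Pearson chi-square — Yates continuity correction for
    2 x 2 tables, uncorrected otherwise. A warning recommends an exact test
    when any expected cell drops below 1.
    """
    cat = pd.Series(clinical_category).reindex(gene_expr.index)
    if cat.nunique() < 2:
        raise ValueError("clinical category needs >= 2 levels")
    if dichotomize != "median":
        raise ValueError("only median dichotomization is implemented")
    cut = gene_expr.median()
    level = pd.Series(np.where(gene_expr > cut, "High", "Low"), index=gene_expr.index)
    table = pd.crosstab(cat, level)
    for col in ("High", "Low"):
        if col not in table.columns:
            table[col] = 0
    table = table[["High", "Low"]]
    stat, p = chi_square_table(table.to_numpy())
    return table, stat, p
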