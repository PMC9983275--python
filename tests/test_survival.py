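"""Cox risk model, stratification, KM/log-rank and clinical associations."""

import numpy as np
import pandas as pd
import pytest

from gcpmir.survival import (
    RiskModel,
    chi_square_association,
    chi_square_table,
    fit_cox,
    risk_stratify,
)

from conftest import make_config, make_null_module


def _binary_covariate_cohort(seed, beta=np.log(2.0), n=500, censor=True):
    """Counts whose log2(x+1) is binary {0, 2}; survival from a Weibull PH
    model with log-hazard beta per SD of that covariate."""
    rng = np.random.default_rng(seed)
    x01 = rng.integers(0, 2, n).astype(float)
    x_std = (x01 - x01.mean()) / x01.std()
    t = 1000.0 * (-np.log(rng.uniform(size=n)) / np.exp(beta * x_std)) ** (1 / 1.2)
    c = rng.uniform(200, 4000, n) if censor else np.full(n, np.inf)
    samples = [f"S{i}" for i in range(n)]
    counts = pd.DataFrame(
        [np.where(x01 > 0, 3.0, 0.0), rng.integers(50, 150, n).astype(float)],
        index=["gene", "filler"], columns=samples,
    )
    ann = pd.DataFrame(
        {
            "survival_time": np.minimum(t, c),
            "event": (t <= c).astype(int),
        },
        index=samples,
    )
    return counts, ann


def test_cox_recovers_binary_log_hazard():
    """Planted hazard ratio 2 per SD: beta-hat within +-0.15 of ln 2 on
    average over seeds."""
    betas = []
    for seed in range(5):
        counts, ann = _binary_covariate_cohort(seed)
        model = fit_cox(counts, ann, ["gene"])
        betas.append(model.coefficients["gene"])
    assert abs(np.mean(betas) - np.log(2.0)) < 0.15


def test_cox_ci_covers_zero_under_null():
    covered = 0
    for seed in range(20):
        counts, ann = _binary_covariate_cohort(seed, beta=0.0, n=300)
        model = fit_cox(counts, ann, ["gene"])
        covered += model.ci_lower["gene"] <= 0.0 <= model.ci_upper["gene"]
    assert covered >= 16


def test_cox_rejects_degenerate_inputs():
    counts, ann = _binary_covariate_cohort(0, n=200)
    flat = counts.copy()
    flat.loc["gene"] = 7.0
    with pytest.raises(ValueError, match="constant"):
        fit_cox(flat, ann, ["gene"])
    with pytest.warns(UserWarning, match="zero-variance"):
        model = fit_cox(flat, ann, ["gene", "filler"])
    assert model.genes == ["filler"]
    with pytest.raises(ValueError, match="missing"):
        fit_cox(counts, ann, ["ghost"])
    few = ann.copy()
    few["event"] = 0
    with pytest.raises(ValueError, match="events"):
        fit_cox(counts, few, ["gene"])


def _identity_model(genes, coefs, cutoff=0.0):
    return RiskModel(
        genes=genes,
        coefficients=dict(zip(genes, coefs)),
        hazard_ratios={g: float(np.exp(c)) for g, c in zip(genes, coefs)},
        ci_lower={g: 0.0 for g in genes},
        ci_upper={g: 0.0 for g in genes},
        cutoff=cutoff,
        scale={g: (0.0, 1.0) for g in genes},
    )


def test_risk_score_zero_and_homogeneity():
    """Zero expression scores 0; scaling the (transformed) expression scales
    the score linearly."""
    model = _identity_model(["g1", "g2"], [0.5, -1.0])
    zeros = pd.DataFrame(0.0, index=["g1", "g2"], columns=["a", "b"])
    assert np.allclose(model.score(zeros), 0.0)
    x = np.array([[1.0, 2.0], [0.5, 3.0]])
    counts = pd.DataFrame(np.power(2.0, x) - 1.0, index=["g1", "g2"], columns=["a", "b"])
    counts2 = pd.DataFrame(np.power(2.0, 2 * x) - 1.0, index=["g1", "g2"], columns=["a", "b"])
    assert np.allclose(model.score(counts2), 2 * model.score(counts))
    with pytest.raises(ValueError, match="missing"):
        model.score(counts.iloc[:1])


def _continuous_covariate_cohort(seed, beta=0.8, n=300, censor=True):
    """Continuous single-gene cohort (risk scores take many values, so the
    median cutoff always yields two non-empty groups)."""
    rng = np.random.default_rng(seed)
    counts_gene = rng.lognormal(4.0, 1.0, n)
    x = np.log2(counts_gene + 1.0)
    x_std = (x - x.mean()) / x.std()
    t = 1000.0 * (-np.log(rng.uniform(size=n)) / np.exp(beta * x_std)) ** (1 / 1.2)
    c = rng.uniform(200, 4000, n) if censor else np.full(n, np.inf)
    samples = [f"S{i}" for i in range(n)]
    counts = pd.DataFrame([counts_gene], index=["gene"], columns=samples)
    ann = pd.DataFrame(
        {"survival_time": np.minimum(t, c), "event": (t <= c).astype(int)},
        index=samples,
    )
    return counts, ann


def test_km_matches_empirical_survival_without_censoring():
    counts, ann = _continuous_covariate_cohort(2, n=120, censor=False)
    model = fit_cox(counts, ann, ["gene"])
    res = risk_stratify(model, counts, ann)
    times = ann["survival_time"]
    for grp in ("high", "low"):
        mask = (res.groups == grp).to_numpy()
        curve = res.km_curves[res.km_curves["group"] == grp]
        t_grp = times[mask].to_numpy()
        for _, row in curve.iterrows():
            empirical = np.mean(t_grp > row["time"])
            assert row["survival"] == pytest.approx(empirical, abs=1e-9)
        assert curve["survival"].iloc[0] == 1.0
        assert curve["survival"].is_monotonic_decreasing


def test_stratification_partitions_and_logrank_detects_separation():
    counts, ann = _continuous_covariate_cohort(4, beta=1.0, n=400)
    model = fit_cox(counts, ann, ["gene"])
    res = risk_stratify(model, counts, ann)
    assert set(res.groups.unique()) == {"high", "low"}
    assert len(res.groups) == 400
    assert res.logrank_p < 0.05


def test_logrank_invariant_under_group_swap():
    counts, ann = _continuous_covariate_cohort(5, beta=0.8, n=300)
    model = fit_cox(counts, ann, ["gene"])
    res = risk_stratify(model, counts, ann)
    flipped = _identity_model(model.genes, [-model.coefficients["gene"]], -model.cutoff)
    flipped.scale = model.scale
    res_fl = risk_stratify(flipped, counts, ann)
    # groups swap roles (up to boundary ties), the test statistic is shared
    assert res_fl.logrank_statistic == pytest.approx(res.logrank_statistic, rel=1e-6)
    assert res_fl.logrank_p == pytest.approx(res.logrank_p, rel=1e-6)


def test_chi_square_2x2_yates_worked_example():
    """Printed 2x2 association table: continuity-corrected chi-square 8.27,
    p = 0.004."""
    stat, p = chi_square_table([[36, 53], [101, 67]])
    assert stat == pytest.approx(8.27, abs=0.01)
    assert p == pytest.approx(0.004, abs=5e-4)


def test_chi_square_association_median_split_extremes():
    rng = np.random.default_rng(0)
    n = 200
    expr = pd.Series(rng.normal(size=n), index=[f"S{i}" for i in range(n)])
    confounded = pd.Series(
        np.where(expr > expr.median(), "A", "B"), index=expr.index
    )
    table, stat, p = chi_square_association(expr, confounded)
    assert p < 1e-20
    assert table.to_numpy().min() == 0
    null_cat = pd.Series(rng.choice(["A", "B"], n), index=expr.index)
    _, _, p_null = chi_square_association(expr, null_cat)
    assert p_null > 1e-6
    with pytest.raises(ValueError, match="levels"):
        chi_square_association(expr, pd.Series("A", index=expr.index))


def test_planted_clinical_association_detected():
    """The age-like category anchored to family A associates with family-A
    miRNA expression far more often than the pure-noise gender category
    does (pooled over cohorts; any one cohort can miss because all family
    members share a single latent factor draw)."""
    from gcpmir.simulate import SimulationConfig, generate_cohort

    hits_planted = hits_null = total = 0
    for seed in range(3):
        cohort, truth = generate_cohort(SimulationConfig(seed=seed))
        fam_a = [m for m, f in truth.family_map.items() if f == "famA"]
        for g in fam_a:
            expr = cohort.counts_mirna.loc[g]
            for cat, bucket in (("age_group", "planted"), ("gender", "null")):
                _, _, p = chi_square_association(expr, cohort.annotations[cat])
                if bucket == "planted":
                    hits_planted += p < 0.05
                    total += 1
                else:
                    hits_null += p < 0.05
    assert hits_planted >= max(3, 0.3 * total)
    assert hits_null <= 0.2 * total


def test_survival_power_on_planted_hazard():
    """Strong planted hazard separates risk groups (log-rank p < 0.05) in
    nearly every seed."""
    from gcpmir.de import normalize_counts
    from gcpmir.simulate import SimulationConfig, generate_cohort

    hits = 0
    for seed in range(5):
        cfg = SimulationConfig(
            n_early=70, n_late=70, n_mirna=30, n_mrna=30, n_lncrna=5,
            extra_de_mirna=0, extra_de_mrna=0, extra_de_lncrna=0, seed=seed,
        )
        cohort, truth = generate_cohort(cfg)
        norm = normalize_counts(cohort.counts_mirna, pseudo_reference=True)
        genes = list(truth.hazard_coefficients)
        model = fit_cox(norm, cohort.annotations, genes)
        res = risk_stratify(model, norm.loc[model.genes], cohort.annotations)
        hits += res.logrank_p < 0.05
    assert hits >= 4
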