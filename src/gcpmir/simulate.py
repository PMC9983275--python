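"""Synthetic TCGA-like cohort generator with planted ground truth.

Emulates the statistical structure the downstream analysis assumes:

* negative-binomial counts around log-normal per-gene baselines;
* stage-differential genes whose means shift by ``2**log2fc`` in the
  late-stage group;
* miRNA families that co-express positively through a shared per-sample
  latent factor;
* miRNA -> target anti-correlation at a configurable Spearman level,
  injected through a Gaussian copula (shared latent factors mapped through
  the NB quantile function), which preserves rank correlation under NB
  noise where direct mean-coupling would not;
* Weibull survival whose log-hazard is a linear predictor of the planted
  miRNAs' standardized expression;
* clinical categories thresholded from gene-linked latent scores so that
  contingency-table associations are plantable.

The generator returns the planted truth (differential genes with signed
effects, the miRNA->target edge list, module membership, hazard
coefficients) so recovery can be measured at every stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FamilySpec",
    "ModuleSpec",
    "ClinicalCategorySpec",
    "SimulationConfig",
    "ExpressionCohort",
    "GroundTruth",
    "InteractionEvidence",
    "generate_cohort",
    "generate_evidence",
]

ESGC = "ESGC"
LSGC = "LSGC"


def _spearman_to_latent(rho_s: float) -> float:
    """Latent (Pearson) correlation of a Gaussian copula that yields a given
    Spearman correlation: rho = 2*sin(pi*rho_s/6)."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


@dataclass
class FamilySpec:
    """A planted miRNA family: members co-express with pairwise Spearman
    correlation ``rho_family`` through a shared latent factor."""

    name: str
    members: List[str]
    rho_family: float = 0.5

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"family {self.name!r} has no members")
        if not 0.0 <= self.rho_family < 1.0:
            raise ValueError("rho_family must be in [0, 1)")


@dataclass
class ModuleSpec:
    """The planted progression module.

    ``shared_mrna_targets`` / ``shared_lncrna_targets`` are regulated by
    every family (this is the structure the module-extraction rule looks
    for); ``private_mrna_targets`` are regulated by a single family.
    Effect sizes are log2 fold changes (late vs early stage).
    """

    families: List[FamilySpec]
    shared_mrna_targets: List[str]
    shared_lncrna_targets: List[str]
    private_mrna_targets: Dict[str, List[str]] = field(default_factory=dict)
    mirna_log2fc: float = -1.2
    target_log2fc: float = 1.0
    rho_plant: float = -0.6

    def __post_init__(self) -> None:
        if self.rho_plant > 0.0:
            raise ValueError("rho_plant must be <= 0 (miRNAs repress targets)")
        if self.rho_plant < -1.0:
            raise ValueError("rho_plant must be >= -1")
        names = {f.name for f in self.families}
        if len(names) != len(self.families):
            raise ValueError("duplicate family names")
        for fam in self.private_mrna_targets:
            if fam not in names:
                raise ValueError(f"private targets reference unknown family {fam!r}")

    @property
    def mirnas(self) -> List[str]:
        return [m for f in self.families for m in f.members]

    @property
    def family_map(self) -> Dict[str, str]:
        return {m: f.name for f in self.families for m in f.members}

    def planted_edges(self) -> List[Tuple[str, str, str]]:
        """(mirna, target, target_class) triples for every planted regulation."""
        edges: List[Tuple[str, str, str]] = []
        for fam in self.families:
            for m in fam.members:
                for t in self.shared_mrna_targets:
                    edges.append((m, t, "mRNA"))
                for t in self.shared_lncrna_targets:
                    edges.append((m, t, "lncRNA"))
                for t in self.private_mrna_targets.get(fam.name, []):
                    edges.append((m, t, "mRNA"))
        return edges


@dataclass
class ClinicalCategorySpec:
    """A categorical clinical variable, optionally associated with the module.

    ``anchor`` names a planted family (the category tracks that family's
    latent factor) or None for a pure-noise category; ``strength`` in [0, 1)
    is the latent correlation between the category score and the anchor.
    ``probs`` are the marginal level frequencies.
    """

    name: str
    levels: List[str]
    probs: List[float]
    anchor: Optional[str] = None
    strength: float = 0.0

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.probs) or len(self.levels) < 2:
            raise ValueError("levels/probs mismatch")
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ValueError("probs must sum to 1")
        if not 0.0 <= self.strength < 1.0:
            raise ValueError("strength must be in [0, 1)")


def default_module_spec() -> ModuleSpec:
    """Two miRNA families (five- and two-member, mirroring the miR-200 and
    miR-183 family sizes), two shared lncRNA targets and nine shared mRNA
    targets, plus a few family-private targets."""
    fam_a = FamilySpec("famA", [f"miR-A-{i}" for i in range(1, 6)], rho_family=0.5)
    fam_b = FamilySpec("famB", [f"miR-B-{i}" for i in range(1, 3)], rho_family=0.5)
    return ModuleSpec(
        families=[fam_a, fam_b],
        shared_mrna_targets=[f"MT-{i:02d}" for i in range(1, 10)],
        shared_lncrna_targets=["LNC-T1", "LNC-T2"],
        private_mrna_targets={
            "famA": [f"PA-{i:02d}" for i in range(1, 5)],
            "famB": [f"PB-{i:02d}" for i in range(1, 3)],
        },
    )


def default_clinical_specs() -> List[ClinicalCategorySpec]:
    return [
        ClinicalCategorySpec(
            "age_group", ["<=60", ">60"], [0.35, 0.65], anchor="famA", strength=0.5
        ),
        ClinicalCategorySpec("gender", ["female", "male"], [0.4, 0.6]),
        ClinicalCategorySpec(
            "grade", ["G1", "G2", "G3"], [0.05, 0.3, 0.65], anchor="famB", strength=0.35
        ),
    ]


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror the reference stomach-cancer cohort: 129 early-stage and
    128 late-stage tumors, with the gene universe scaled down to keep the
    whole pipeline runnable in minutes.
    """

    n_early: int = 129
    n_late: int = 128
    n_mirna: int = 60
    n_mrna: int = 300
    n_lncrna: int = 20
    module: ModuleSpec = field(default_factory=default_module_spec)
    extra_de_mirna: int = 10
    extra_de_mrna: int = 40
    extra_de_lncrna: int = 3
    extra_de_log2fc: float = 1.0
    nb_dispersion: float = 0.2
    baseline_log_mean: float = 4.5
    baseline_log_sd: float = 1.0
    evidence_sensitivity: float = 0.9
    evidence_specificity: float = 0.995
    weibull_scale: float = 1500.0
    weibull_shape: float = 1.2
    censor_low: float = 300.0
    censor_high: float = 3650.0
    hazard_coefficients: Optional[Dict[str, float]] = None
    clinical: List[ClinicalCategorySpec] = field(default_factory=default_clinical_specs)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_early", "n_late", "n_mirna", "n_mrna", "n_lncrna"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("evidence_sensitivity", "evidence_specificity"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.weibull_scale <= 0 or self.weibull_shape <= 0:
            raise ValueError("Weibull baseline parameters must be positive")
        spec = self.module
        if len(spec.mirnas) > self.n_mirna:
            raise ValueError("more planted miRNAs than n_mirna")
        n_planted_mrna = len(spec.shared_mrna_targets) + sum(
            len(v) for v in spec.private_mrna_targets.values()
        )
        if n_planted_mrna > self.n_mrna:
            raise ValueError("more planted mRNA targets than n_mrna")
        if len(spec.shared_lncrna_targets) > self.n_lncrna:
            raise ValueError("more planted lncRNA targets than n_lncrna")
        fam_names = {f.name for f in spec.families}
        for cat in self.clinical:
            if cat.anchor is not None and cat.anchor not in fam_names:
                raise ValueError(
                    f"clinical category {cat.name!r} anchored to unknown family {cat.anchor!r}"
                )

    def resolved_hazard_coefficients(self) -> Dict[str, float]:
        if self.hazard_coefficients is not None:
            return dict(self.hazard_coefficients)
        return {m: 0.35 for m in self.module.mirnas}


@dataclass
class ExpressionCohort:
    """Three genes x samples count matrices plus per-sample annotations.

    ``annotations`` is indexed by sample id and carries ``group`` (ESGC /
    LSGC), ``survival_time`` (days), ``event`` (1 = death observed) and the
    clinical category columns.
    """

    counts_mirna: pd.DataFrame
    counts_mrna: pd.DataFrame
    counts_lncrna: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        cols = list(self.counts_mirna.columns)
        if list(self.counts_mrna.columns) != cols or list(self.counts_lncrna.columns) != cols:
            raise ValueError("sample columns differ between RNA classes")
        if list(self.annotations.index) != cols:
            raise ValueError("annotation index does not match sample columns")
        ids = (
            list(self.counts_mirna.index)
            + list(self.counts_mrna.index)
            + list(self.counts_lncrna.index)
        )
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate gene ids across RNA classes")
        t = self.annotations["survival_time"]
        if (t.dropna() <= 0).any():
            raise ValueError("survival_time must be positive")

    @property
    def sample_ids(self) -> List[str]:
        return list(self.counts_mirna.columns)

    @property
    def group(self) -> pd.Series:
        return self.annotations["group"]

    def counts(self, rna_class: str) -> pd.DataFrame:
        return {
            "miRNA": self.counts_mirna,
            "mRNA": self.counts_mrna,
            "lncRNA": self.counts_lncrna,
        }[rna_class]


@dataclass
class GroundTruth:
    """What was planted, for recovery scoring."""

    de_effects: Dict[str, Dict[str, float]]  # rna_class -> gene -> log2fc
    planted_edges: List[Tuple[str, str, str]]  # (mirna, target, target_class)
    family_map: Dict[str, str]  # planted miRNA -> family name
    module_mrnas: List[str]  # shared (both-family) mRNA targets
    module_lncrnas: List[str]
    hazard_coefficients: Dict[str, float]

    def __post_init__(self) -> None:
        genes = set()
        for d in self.de_effects.values():
            genes.update(d)
        for m, t, _ in self.planted_edges:
            if m not in self.family_map:
                raise ValueError(f"planted edge references unknown miRNA {m!r}")


@dataclass
class InteractionEvidence:
    """Target-prediction evidence tables.

    ``mrna``: columns (mirna_id, target_id, score) with a 0-100 prediction
    score; ``lncrna``: columns (mirna_id, target_id, source) — boolean
    presence per database-like source.
    """

    mrna: pd.DataFrame
    lncrna: pd.DataFrame


def _assign_gene_ids(config: SimulationConfig) -> Dict[str, List[str]]:
    spec = config.module
    mirnas = list(spec.mirnas)
    mirnas += [f"miR-bg-{i:03d}" for i in range(1, config.n_mirna - len(mirnas) + 1)]
    planted_mrna = list(spec.shared_mrna_targets)
    for fam in sorted(spec.private_mrna_targets):
        planted_mrna += spec.private_mrna_targets[fam]
    mrnas = planted_mrna + [
        f"GENE-{i:04d}" for i in range(1, config.n_mrna - len(planted_mrna) + 1)
    ]
    lncrnas = list(spec.shared_lncrna_targets)
    lncrnas += [f"LNC-bg-{i:03d}" for i in range(1, config.n_lncrna - len(lncrnas) + 1)]
    return {"miRNA": mirnas, "mRNA": mrnas, "lncRNA": lncrnas}


def _planted_effects(
    config: SimulationConfig, ids: Dict[str, List[str]], rng: np.random.Generator
) -> Dict[str, Dict[str, float]]:
    spec = config.module
    effects: Dict[str, Dict[str, float]] = {"miRNA": {}, "mRNA": {}, "lncRNA": {}}
    for m in spec.mirnas:
        effects["miRNA"][m] = spec.mirna_log2fc
    targets_mrna = list(spec.shared_mrna_targets) + [
        t for fam in sorted(spec.private_mrna_targets) for t in spec.private_mrna_targets[fam]
    ]
    for t in targets_mrna:
        effects["mRNA"][t] = spec.target_log2fc
    for t in spec.shared_lncrna_targets:
        effects["lncRNA"][t] = spec.target_log2fc
    # extra (non-module) stage-differential genes with random sign
    for rna_class, n_extra in (
        ("miRNA", config.extra_de_mirna),
        ("mRNA", config.extra_de_mrna),
        ("lncRNA", config.extra_de_lncrna),
    ):
        background = [g for g in ids[rna_class] if g not in effects[rna_class]]
        n_extra = min(n_extra, len(background))
        chosen = rng.choice(background, size=n_extra, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_extra)
        for g, s in zip(chosen, signs):
            effects[rna_class][str(g)] = s * config.extra_de_log2fc
    return effects


def _latent_matrix(
    config: SimulationConfig,
    ids: Dict[str, List[str]],
    n_samples: int,
    rng: np.random.Generator,
) -> Tuple[Dict[str, np.ndarray], Dict[str, np.ndarray]]:
    """Gaussian latent variables per gene, with family factors and planted
    miRNA->target anti-coupling. Returns (latents per class, family factors)."""
    spec = config.module
    z = {
        cls: rng.standard_normal((len(ids[cls]), n_samples)) for cls in ids
    }
    row = {cls: {g: i for i, g in enumerate(ids[cls])} for cls in ids}
    factors: Dict[str, np.ndarray] = {
        f.name: rng.standard_normal(n_samples) for f in spec.families
    }
    loading: Dict[str, float] = {}
    for fam in spec.families:
        a = math.sqrt(max(_spearman_to_latent(fam.rho_family), 0.0))
        loading[fam.name] = a
        for m in fam.members:
            i = row["miRNA"][m]
            eps = z["miRNA"][i]
            z["miRNA"][i] = a * factors[fam.name] + math.sqrt(1.0 - a * a) * eps
    rho_l = abs(_spearman_to_latent(spec.rho_plant))
    target_fams: Dict[Tuple[str, str], List[str]] = {}
    for fam in spec.families:
        for t in spec.shared_mrna_targets:
            target_fams.setdefault((t, "mRNA"), []).append(fam.name)
        for t in spec.shared_lncrna_targets:
            target_fams.setdefault((t, "lncRNA"), []).append(fam.name)
        for t in spec.private_mrna_targets.get(fam.name, []):
            target_fams.setdefault((t, "mRNA"), []).append(fam.name)
    # remove duplicates while keeping order
    for key, fams in target_fams.items():
        target_fams[key] = list(dict.fromkeys(fams))
    for (t, cls), fams in target_fams.items():
        nf = len(fams)
        u = sum(factors[f] for f in fams) / math.sqrt(nf)
        a_min = min(loading[f] for f in fams)
        if rho_l == 0.0 or a_min == 0.0:
            continue
        # b chosen so that per-pair latent corr = b*a/sqrt(nf) hits rho_l;
        # capped at 1 when the family loading cannot support it (the
        # achieved anti-correlation is then a_min/sqrt(nf), documented).
        b = min(1.0, rho_l * math.sqrt(nf) / a_min)
        i = row[cls][t]
        eps = z[cls][i]
        z[cls][i] = -b * u + math.sqrt(1.0 - b * b) * eps
    return z, factors


def _counts_from_latent(
    z: np.ndarray,
    log_mu: np.ndarray,
    effects: np.ndarray,
    is_late: np.ndarray,
    dispersion: float,
) -> np.ndarray:
    """Map latent Gaussians through the NB quantile function (Gaussian
    copula), with stage effects entering the NB mean multiplicatively."""
    mu = np.exp(log_mu)[:, None] * np.power(2.0, np.outer(effects, is_late))
    u = stats.norm.cdf(z)
    u = np.clip(u, 1e-12, 1.0 - 1e-10)
    r = 1.0 / dispersion
    p = r / (r + mu)
    counts = stats.nbinom.ppf(u, r, p)
    return counts.astype(np.int64)


def generate_cohort(config: SimulationConfig) -> Tuple[ExpressionCohort, GroundTruth]:
    """Draw a full synthetic cohort plus its ground truth.

    Deterministic given ``config.seed``: the same config yields bit-identical
    matrices.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_early + config.n_late
    sample_ids = [f"S{i:04d}" for i in range(1, n + 1)]
    is_late = np.array([0] * config.n_early + [1] * config.n_late, dtype=float)
    group = np.where(is_late > 0, LSGC, ESGC)

    ids = _assign_gene_ids(config)
    effects = _planted_effects(config, ids, rng)
    z, factors = _latent_matrix(config, ids, n, rng)

    counts: Dict[str, pd.DataFrame] = {}
    for cls in ("miRNA", "mRNA", "lncRNA"):
        genes = ids[cls]
        log_mu = rng.normal(config.baseline_log_mean, config.baseline_log_sd, len(genes))
        eff = np.array([effects[cls].get(g, 0.0) for g in genes])
        mat = _counts_from_latent(z[cls], log_mu, eff, is_late, config.nb_dispersion)
        counts[cls] = pd.DataFrame(mat, index=genes, columns=sample_ids)

    # Weibull proportional-hazards survival driven by planted miRNA expression
    hz = config.resolved_hazard_coefficients()
    lp = np.zeros(n)
    for gene, beta in hz.items():
        x = np.log2(counts["miRNA"].loc[gene].to_numpy(dtype=float) + 1.0)
        sd = x.std()
        if sd > 0:
            lp += beta * (x - x.mean()) / sd
    u = rng.uniform(size=n)
    t_event = config.weibull_scale * np.power(
        -np.log(u) / np.exp(lp), 1.0 / config.weibull_shape
    )
    t_cens = rng.uniform(config.censor_low, config.censor_high, size=n)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(np.minimum(t_event, t_cens), 1.0)

    ann = pd.DataFrame(
        {"group": group, "survival_time": np.round(time, 1), "event": event},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    for cat in config.clinical:
        if cat.anchor is not None and cat.strength > 0:
            anchor = factors[cat.anchor]
            s = cat.strength * anchor + math.sqrt(1 - cat.strength**2) * rng.standard_normal(n)
        else:
            s = rng.standard_normal(n)
        cuts = stats.norm.ppf(np.cumsum(cat.probs)[:-1])
        idx = np.searchsorted(cuts, s)
        ann[cat.name] = [cat.levels[i] for i in idx]

    cohort = ExpressionCohort(counts["miRNA"], counts["mRNA"], counts["lncRNA"], ann)
    truth = GroundTruth(
        de_effects=effects,
        planted_edges=config.module.planted_edges(),
        family_map=config.module.family_map,
        module_mrnas=list(config.module.shared_mrna_targets),
        module_lncrnas=list(config.module.shared_lncrna_targets),
        hazard_coefficients=hz,
    )
    return cohort, truth


def generate_evidence(
    truth: GroundTruth, config: SimulationConfig
) -> InteractionEvidence:
    """Emulated target-prediction tables.

    Each planted edge is reported with probability ``evidence_sensitivity``
    (mRNA targets get a prediction score uniform on (51, 100)); each
    non-edge appears with probability ``1 - evidence_specificity`` with a
    score uniform on (0, 100). lncRNA evidence is boolean, tagged with a
    database-like source.
    """
    rng = np.random.default_rng([config.seed, 9151])
    ids = _assign_gene_ids(config)
    planted = {(m, t): cls for m, t, cls in truth.planted_edges}

    rows_m: List[Tuple[str, str, float]] = []
    rows_l: List[Tuple[str, str, str]] = []
    sources = ("starbase_like", "lncbase_like")
    for mirna in ids["miRNA"]:
        for target in ids["mRNA"]:
            if planted.get((mirna, target)) == "mRNA":
                if rng.uniform() < config.evidence_sensitivity:
                    rows_m.append((mirna, target, float(rng.uniform(51.0, 100.0))))
            elif rng.uniform() < 1.0 - config.evidence_specificity:
                rows_m.append((mirna, target, float(rng.uniform(0.0, 100.0))))
        for target in ids["lncRNA"]:
            if planted.get((mirna, target)) == "lncRNA":
                if rng.uniform() < config.evidence_sensitivity:
                    rows_l.append((mirna, target, sources[int(rng.integers(2))]))
            elif rng.uniform() < 1.0 - config.evidence_specificity:
                rows_l.append((mirna, target, sources[int(rng.integers(2))]))
    mrna = pd.DataFrame(rows_m, columns=["mirna_id", "target_id", "score"])
    lncrna = pd.DataFrame(rows_l, columns=["mirna_id", "target_id", "source"])
    return InteractionEvidence(mrna=mrna, lncrna=lncrna)
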