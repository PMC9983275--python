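# Methods

## Scope and data model

The package operates on three non-negative count matrices (miRNA, mRNA,
lncRNA; genes × samples, shared sample columns, globally unique gene ids), a
sample annotation table (stage group ESGC/LSGC, survival time in days,
event indicator, categorical clinical columns) and two interaction-evidence
tables (scored miRNA→mRNA predictions on a 0–100 scale; boolean
miRNA→lncRNA predictions with a source tag). All quantities the pipeline
reports are recomputed from these inputs; nothing is looked up.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, and
only that structure:

* **Counts.** Gene *g* in sample *j* is NB(μ_gj, α) with a single global
  dispersion α (default 0.2) and μ_gj = baseline_g · 2^(effect_g · late_j).
  Baselines are log-normal (log-mean 4.5, log-sd 1.0 → counts of order
  10–10³). Planted differential genes shift multiplicatively in the
  late-stage group; module miRNAs default to log2FC −1.2 and their targets
  to +1.0, with additional background differential genes at |log2FC| 1.
* **Dependence** is injected through a Gaussian copula: latent standard
  normals are mapped through the NB quantile function, so rank-based
  statistics see the planted correlation essentially unattenuated (the
  latent Pearson correlation is set to 2·sin(π·ρ_s/6) for a target
  Spearman ρ_s). Family members load on a shared per-sample factor
  (pairwise Spearman 0.5 by default); each planted target loads negatively
  on the (combined) factor of the families that regulate it, scaled so the
  per-pair miRNA–target Spearman approaches `rho_plant` (default −0.6).
  Two feasibility constraints follow from this construction and are
  enforced by clipping: a target's achievable |SCC| with a member of one
  family cannot exceed a (the member loading), and with two regulating
  families it cannot exceed a/√2 — shared ceRNA targets are genuinely less
  tightly coupled to any single miRNA. Pooled-cohort correlations are
  further strengthened by the opposite-sign stage effects, which is the
  regime the network filters exploit.
* **Survival** is Weibull proportional hazards (scale 1500 days, shape
  1.2): T = scale · (−ln U · e^(−lp))^(1/shape) with lp = Σ β_g ·
  z(log2(count_g + 1)) over the planted miRNAs (default β = 0.35 each),
  independently censored uniform(300, 3650) days.
* **Clinical categories** threshold a latent score that mixes a family
  factor with noise (`strength` = latent correlation), at the normal
  quantiles of the requested marginal frequencies — so chi-square
  associations between module-gene expression and a category are plantable
  with known strength, while unlinked categories are exactly null.
* **Evidence.** Each planted edge is reported with probability
  `evidence_sensitivity` (mRNA scores uniform(51, 100)); each non-edge
  appears with probability 1 − `evidence_specificity` (scores
  uniform(0, 100)). Defaults 0.9 / 0.995.

What the generator does **not** emulate: read-level noise, library-size
artefacts beyond random depth variation, batch effects, per-gene dispersion
trends, copy-number/methylation layers, or non-proportional hazards.
Passing tests therefore demonstrate correctness of the analysis machinery
under the stated model, not robustness to those real-data phenomena.

## Differential screen

Size factors are median-of-ratios (each sample's median ratio to the
per-gene geometric mean over samples; genes with any zero drop out of the
reference, with an explicit pseudo-reference fallback). The default test is
a negative-binomial Wald test: per-group means on normalized counts, pooled
method-of-moments dispersion α̂ = (s² − μ̂)/μ̂² averaged over groups and
clipped at 0, Var(log μ̂) by the delta method, and a t reference with
n₁+n₂−2 df. log2 fold changes use a 0.5 pseudo-count. BH adjustment is per
RNA class. A Wilcoxon rank-sum engine is available (`method="wilcoxon"`;
constant genes get p = 1, not an error).

Calibration: the null type-I error measures ~0.049 at n = 60/60 and the
BH-significant fraction under the full null is far below 0.075. A known
limitation: with strong signal present, the method-of-moments Wald is
mildly anticonservative in the extreme tail, so the realized FDR among
calls can exceed the nominal 5% (0.07–0.19 observed at the default
conditions). Dispersion shrinkage and independent filtering are
deliberately out of scope; the screen is a candidate filter ahead of the
correlation-plus-evidence network stage, which removes chance calls.

## Network construction and topology

All thresholds are strict inequalities: Spearman retention p < 0.05 (t
approximation, average-rank ties; constant genes skipped with a warning),
miRNA–mRNA edges SCC < −0.3 **and** prediction score > 50, miRNA–lncRNA
edges SCC < −0.3 or (SCC < 0 and predicted). Correlations pool both stage
groups: differential direction and correlation sign are only jointly
interpretable on the pooled tumor cohort, and the group-shift contribution
to anti-correlation is part of the signal. The ceRNA closure keeps only
miRNAs with at least one partner of each class (disable with
`cerna_closure=False`); an empty result is a status, not an exception.

Topology is computed per connected component on the unweighted undirected
graph: degree D, total shortest-path length L (BFS), closeness
C = (N_c − 1)/L, betweenness normalized by (N_c − 1)(N_c − 2)/2. The
closeness convention was chosen because inverting the published
prioritization table under C = (N−1)/L yields integer L for all ten rows,
which the reciprocal-sum convention does not; the same inversion yields
integer Rs bounded by N − 1, supporting the rank reading of the SVM-RFE
score. Singleton components are flagged and excluded from scoring.

## RNs prioritization

Expression enters SVM-RFE as log2(x+1), per-gene z-scored. The SVM is
linear with C = 1, elimination step 1, ties in squared weight broken
lexicographically so the ranking is deterministic; chunked elimination is
available via `step`. Rs = n − rank + 1. RNs = K·Rs/L exactly, with
3-decimal rounding only at report time; ties in the top-k selection break
toward higher degree, then lexicographic id.

## Module extraction and validation

"Regulated by both families" is read as ≥ 1 edge to each family (the
weakest reading consistent with the rule; `min_edges_per_family` is
configurable). Validation recomputes Spearman per module edge on an
independent expression matrix — the green flag requires SCC < −0.5 and
p < 0.05, both strict — and contrasts each gene between sample groups with
a two-sided Wilcoxon rank-sum test. Genes missing from the validation set
are reported, never silently dropped.

## Survival and clinical association

Cox fits use lifelines (Efron ties) on log2(normalized count + 1), per-gene
z-scored on the training cohort; the scale parameters are stored in the
model so held-out cohorts are scored reproducibly. The high/low cutoff
defaults to the training-cohort median risk score ("mean" or an explicit
value are accepted). Fewer than 10 observed events is an error;
zero-variance genes are dropped with a warning. Stratification reports
Kaplan–Meier curves per group and the 1-df log-rank test.

Chi-square association median-splits expression into High/Low and tests
the r×2 table — Yates-corrected when 2×2 (this choice reproduces the
published worked value p = 0.004 on the printed age table), uncorrected
otherwise. The continuity correction is conservative by construction at
small n (type-I ≈ 0.03 at n = 60, approaching nominal by n = 400); the
calibration experiment therefore checks the uncorrected path in the
nominal band and bounds the corrected path at ≤ nominal.

## Progression classifier

The 7:3 split is a seeded simple random partition (round(0.7·257) = 180 /
77). Every non-empty subset of the gene panel (≤ 20 genes; 2¹⁴ − 1 = 16383
for a 14-gene module) trains SVC(linear, C = 1) on training-standardized
features; test decision values feed the ROC and the AUC is the
Mann–Whitney U / (n₁n₀) with ties at ½ (the trapezoidal area of the stored
ROC equals it; both routes are computed and compared in the tests).
Ranking ties break toward smaller subsets, then lexicographic gene tuples.

Under a permuted-label null the mean subset AUC centers at 0.5, but the
*maximum* over thousands of subsets is upward-biased by selection even
when no signal exists; an observed best AUC is therefore only meaningful
against that permutation distribution of maxima, and the evaluation module
reports both.

## Problem sizes and experiment design

Default study conditions: 129 early + 128 late samples; a 60/300/20 gene
universe around a two-family module (5 + 2 miRNAs, 9 shared mRNA targets,
2 lncRNA targets, 6 family-private targets). The recovery experiments use:
planted-edge F1 on a 30/100/10 universe with high-quality evidence
(sensitivity 0.98, specificity 0.999), 20–50 seeds; Cox recovery with one
planted β = 0.6 at n = 1000 (50 background miRNAs so size factors are
stable — normalization with a handful of genes visibly attenuates β̂);
type-I calibration at 1000 replicates; subset recovery on a 10-gene panel
(6 independent signal genes at log2FC 0.7 — chosen so the best subset
lands near AUC 0.9 rather than saturating, since perfectly redundant or
perfectly separable panels make the argmax subset arbitrary — plus 4
nulls) over 10 seeds.

## Known limitations

* MoM-dispersion Wald tails (above); use `method="wilcoxon"` when FDR
  among calls matters more than power.
* The generator's single global dispersion and Gaussian-copula dependence
  are idealizations; per-gene dispersion is configurable but untrended.
* Exhaustive subset search is exponential and capped at 20 genes.
* Family membership is treated as prior knowledge (nomenclature), not
  inferred from sequence.
* No penalized Cox, time-dependent covariates or competing risks; no GO /
  KEGG enrichment; prediction databases are consumed as evidence tables,
  never queried.
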