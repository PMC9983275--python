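# gcpmir

Network-module discovery for gastric-cancer (GC) progression from paired
miRNA / mRNA / lncRNA expression cohorts.

Late-stage gastric cancer is driven in part by competitive-endogenous-RNA
(ceRNA) regulation: lncRNAs and mRNAs that share miRNA response elements are
co-regulated by the same miRNAs, and progression-associated modules of this
network are candidate biomarkers. `gcpmir` implements that analysis as a
reusable, tested pipeline for bioinformaticians who want to run it on
TCGA-style cohorts (genes × samples count matrices with stage, survival and
clinicopathological annotations) — or on synthetic cohorts with planted
ground truth, which the package generates itself so every stage is testable
without patient data.

## The method

1. **Differential screen.** Each RNA class is screened for genes
   differentially expressed between early-stage (ESGC, TNM I–II) and
   late-stage (LSGC, TNM III–IV) tumors: median-of-ratios normalization,
   a negative-binomial Wald test with method-of-moments dispersion (or
   Wilcoxon), Benjamini–Hochberg within each class, adjusted *p* < 0.05.
2. **Progression network.** Among differential genes, miRNA–partner pairs
   are scored with Spearman correlation (keep *p* < 0.05). miRNA–mRNA edges
   require SCC < −0.3 **and** a target-prediction score > 50; miRNA–lncRNA
   edges require SCC < −0.3, or SCC < 0 plus a database prediction. The
   ceRNA closure then keeps only miRNAs with both an mRNA and an lncRNA
   partner.
3. **RNs prioritization.** Each node is scored

   RNs = K · Rs / L

   where K is its degree, L the total shortest-path length to the other
   nodes of its component (so closeness C = (N−1)/L), and Rs the SVM-RFE
   rank score of its expression (linear SVM, recursive elimination of the
   smallest-weight feature; the gene eliminated last among n features gets
   Rs = n). RNs rewards central hubs whose expression separates the stage
   groups.
4. **Module extraction.** The prioritized miRNAs carry family tags (e.g.
   the miR-200 and miR-183 families); every network mRNA adjacent to at
   least one member of *each* family joins the module, together with the
   prioritized lncRNAs and the induced edges.
5. **Risk stratification.** A multivariable Cox model on the module miRNAs
   yields a risk score Σ βᵢxᵢ; patients above the training-cohort median
   form the high-risk group, compared by Kaplan–Meier / log-rank.
   Clinicopathological associations use chi-square on high/low ×
   category tables (Yates-corrected when 2×2).
6. **Progression classifier.** Every non-empty subset of the module gene
   panel trains a linear SVM on the training cohort; held-out decision
   values give a ROC whose AUC (Mann–Whitney identity) ranks the subsets.

## Worked example

```python
from gcpmir import PipelineConfig, SimulationConfig, run_pipeline

bundle = run_pipeline(PipelineConfig(simulation=SimulationConfig(seed=7)))
```

The default configuration simulates a 257-patient cohort (129 early-stage,
128 late-stage) with a planted two-family module. The run prints / returns:

```
status: ok
network: 27 nodes, 106 edges (edge-recovery F1 0.899)
top genes by RNs: miR-A-5, miR-A-1, miR-A-4, miR-B-1, miR-A-2 ...
module: 6 miRNAs, 3 lncRNAs, 8 mRNAs
rns table head:
          K   L    Rs    RNs
miR-A-5  16  40  23.0  9.200
miR-A-1  17  38  19.0  8.500
miR-A-4  16  40  21.0  8.400
miR-B-1  13  46  20.0  5.652
miR-A-2  16  40  14.0  5.600
log-rank p (train/test/whole): 3.50e-26 / 8.50e-13 / 6.48e-38
best subset (7 genes): miR-A-5, miR-A-4, miR-B-1, miR-A-3, MT-01, MT-03, MT-04  AUC = 0.997
```

Reading this: the four-step construction recovered the planted regulations
with F1 0.90; the RNs ranking surfaces the planted family miRNAs (K·Rs/L,
e.g. 16·23/40 = 9.200); the extracted module separates survival of the
planted-hazard cohort in training, held-out and pooled patients; and the
exhaustive subset search finds a high-AUC panel dominated by planted genes.
Every matrix, table, model and a manifest of file hashes can be written to
disk by passing `outdir=...` (or via the CLI below).

The same stages are available from the shell:

```bash
gcpmir simulate --outdir sim --seed 3            # cohort + evidence + truth
gcpmir de --counts sim/counts_mrna.tsv --annotations sim/annotations.tsv \
          --class mRNA --out de_mrna.tsv
gcpmir network --indir sim --out net.graphml
gcpmir run --outdir bundle --seed 3              # everything, with manifest
```

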