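# krassig

Tools for identifying and scoring a mutant-KRAS-associated tumor epithelial
subpopulation from single-cell and bulk RNA-seq, built around the analysis
recipe used to characterize the C10 cluster in KRAS-mutant lung
adenocarcinoma: mode-based cell filtering, MAD outlier rules, doublet
exclusion, kNN-graph Leiden clustering, hybrid two-reference cell-type
annotation, negative-binomial likelihood-ratio differential expression, a
cross-species homolog signature, and per-cell / per-cohort signature scoring
with median-split survival analysis.

The package is aimed at computational biologists who want those bespoke
steps — which are described in prose in the literature but not shipped as
reusable code — as tested, deterministic functions, together with a
synthetic-data module that generates inputs with the same statistical
structure (debris-dominated barcode totals, planted tumor cluster,
21-up/9-down signature, survival cohorts) so the whole pipeline can be
exercised without any data download.

## The statistics at the core

**Cell filtering.** Cells with total counts below a trim threshold derived
from the mode m of the per-sample total-count distribution are removed:

    m < 100        : threshold = m × 5.5
    100 ≤ m ≤ 450  : threshold = (−0.01·m + 6.5)        (printed rule)
    m > 450        : threshold = m × 2

The printed middle branch is discontinuous with its neighbors; by default
the package reads it as a *multiplier* of m, which makes the rule continuous
(550 at m = 100, 900 at m = 450). Both readings are available
(`trim_threshold(m, interpretation=...)`). Survivors then pass raw-MAD
outlier filters (library size −3/+6, detected genes −2/+5, mitochondrial
percentage +6 MADs from the median) and a simulated-doublet kNN score with
the 0.99 exclusion cutoff.

**Differential expression.** Genewise two-group negative-binomial
likelihood-ratio test: moment dispersions (variance μ + αμ²) shrunk 30%
toward the global median, maximum-likelihood group means under null and
alternative at fixed dispersion, LRT against χ²₁, Benjamini–Hochberg FDR.

**Signature.** Homolog pairs with log2FC ≥ 1.5 (up) or ≤ −1.5 (down) and
FDR ≤ 0.05 in the tumor-cluster-vs-other-epithelium contrast of *both*
species. Per cell, the enrichment score is the fraction of signature genes
detected (1 = all detected). Per cohort sample, the score is the mean of
per-gene z-scores with down-gene z-scores sign-flipped; the cohort median
splits samples into low/high groups compared by Kaplan–Meier, log-rank and
a single-covariate Cox model (Efron ties).

## Worked example

```python
import numpy as np
from krassig import (SimConfig, QCConfig, generate_sc_dataset, apply_qc_filters,
                     size_factors, normalize_log, knn_graph, cluster_cells,
                     nb_glm_lrt, derive_common_signature, HomologMap,
                     CohortConfig, generate_cohort, cohort_signature_score,
                     median_split, survival_analysis, two_group_t)

matrix, truth = generate_sc_dataset(SimConfig(seed=1))
filtered, qc_table, report = apply_qc_filters(matrix, QCConfig(seed=0))
print(f"QC: {report['n_input']} barcodes -> {report['n_output']} cells "
      f"(mode {report['mode_estimate']:.0f}, trim threshold {report['trim_threshold']:.0f})")

factors = size_factors(filtered)
norm = normalize_log(filtered, factors)
labels = cluster_cells(knn_graph(norm, k=15, seed=0), seed=0)
print(f"Leiden: {labels.n_clusters} clusters")

grp = np.array([truth.true_cluster_per_cell[matrix.cell_ids.index(c)] == 0
                for c in filtered.cell_ids])
de = nb_glm_lrt(filtered.counts[:, np.flatnonzero(grp)],
                filtered.counts[:, np.flatnonzero(~grp)],
                factors[grp], factors[~grp], gene_ids=filtered.gene_ids)
sig = derive_common_signature(de, de, HomologMap(filtered.gene_ids, filtered.gene_ids))
print(f"planted genes recovered: "
      f"{len(set(sig.up_genes) & set(truth.signature_up_genes))}/21 up, "
      f"{len(set(sig.down_genes) & set(truth.signature_down_genes))}/9 down")

cohort = generate_cohort(CohortConfig(seed=0))
score = cohort_signature_score(cohort.expression, cohort.signature_up, cohort.signature_down)
mut = (cohort.clinical.mutation_status == "mutant").to_numpy()
t, p = two_group_t(score[mut], score[~mut])
print(f"cohort: mutant vs WT t = {t:.1f}, p = {p:.2e}")
group = median_split(score)
res = survival_analysis(cohort.clinical.os_time, cohort.clinical.event.astype(bool),
                        group.to_numpy())
print(f"survival: log-rank p = {res.logrank_p:.2e}, hazard ratio = {res.hazard_ratio:.2f}")
```

prints

```
QC: 630 barcodes -> 275 cells (mode 592, trim threshold 1184)
Leiden: 3 clusters
planted genes recovered: 21/21 up, 9/9 down
cohort: mutant vs WT t = 45.8, p = 1.43e-106
survival: log-rank p = 3.26e-13, hazard ratio = 2.78
```

The 630 columns are 600 barcodes plus 30 doublets; the trim threshold (2×
the debris mode) removes the planted debris population, the MAD and doublet
rules catch the remaining outliers, Leiden recovers the three simulated cell
populations, and the cross-species derivation returns every planted
signature gene. In the bulk cohort, mutant samples score far above
wild-type, and the signature-high group has roughly 2.8-fold higher hazard
— the directionality the signature is designed to capture.

Every stage is also a CLI subcommand
(`krassig simulate | qc | normalize | cluster | annotate | composition |
de | signature | score-cells | score-cohort | survival`); run
`krassig --help` for the formats each expects.

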