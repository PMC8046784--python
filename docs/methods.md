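# Methods

This note documents the models, numerical choices and known limitations of
the pipeline. Everything stated here is computed by the test suite or the
worked examples; nothing is quoted from external results.

## Cell filtering

### The mode-based trim rule and its two readings

The minimum-counts threshold is a piecewise function of the mode m of the
per-sample total-count distribution: m×5.5 below 100; (−0.01·m + 6.5)
between 100 and 450; m×2 above 450. Read literally, the middle branch is an
absolute count of 2–6.5 and is discontinuous with both flanking branches
(which give 550 at m = 100 and 900 at m = 450). The default
`continuous_multiplier` interpretation treats the middle expression as a
multiplier of m, which restores continuity at both breakpoints and makes
the threshold strictly increasing in m. Both readings are implemented
behind the `interpretation` switch.

The two readings imply different operating regimes, and this matters for
testing:

* Under the multiplier reading, the threshold is always at least 2× the
  density mode, so the cells *at* the mode are always removed. The rule is
  therefore only sensible when the mode sits on a **debris peak** well below
  the genuine cells — the situation in raw droplet-based gene-cell matrices,
  where sub-cell barcodes outnumber real cells. The threshold then lands in
  the trough between debris and cells, implementing a knee-point cut.
* Under the literal reading (for modes in [100, 450]) the threshold is a
  few counts and only removes near-empty barcodes. Fixtures that need a
  filter-neutral trim (the "every cell passes" identity case and the
  idempotence check) use this reading.

### Mode estimation

The mode estimator is a Gaussian kernel density estimate with Silverman
bandwidth fitted to log10(total+1), maximized on a 4096-point grid and
back-transformed. It is fully deterministic; a degenerate (constant) input
returns the constant. The estimator used in the original workflow is not
specified; KDE-on-log is the natural smooth choice and is validated against
a dense-grid brute-force argmax in the tests.

### MAD rules

Outlier bounds are median ± n·MAD with the **raw** median absolute
deviation — no 1.4826 Gaussian consistency constant, no log transform —
with n = (3, 6) for library size, (2, 5) for detected genes, and (–, 6) for
mitochondrial percentage. Both conventions are configurable (`mad_scale`).
All MAD statistics are computed once on the post-trim population and the
three rules are applied to it jointly; they are population-dependent, so
re-running the filter on its own output can remove further cells (the trim
and doublet steps, by contrast, are idempotent in the literal regime).

A quantitative caveat the tests make explicit: "2 raw MADs below the
median" sits at the 8.8% point of a Gaussian, so these rules remove 5–9% of
*any* smooth unimodal population. They behave as intended — removing only a
few percent — when the metrics are flat-topped mixtures across cell types
with different RNA content, which is both the realistic situation and the
regime the synthetic data emulate.

### Doublet score

The cited doublet-scoring algorithm is not described in the source
workflow, so a documented stand-in is used: `n_simulated` artificial
doublets (default one per cell) are formed by summing random distinct cell
pairs; all columns are total-count normalized to the median library size,
log1p-transformed and embedded by PCA (20 PCs); the raw statistic is the
fraction of a cell's k = 20 nearest neighbors that are simulated. The
*returned score* is the empirical CDF (average rank / n) of that fraction,
so the published cutoff of 0.99 excludes the top 1% most doublet-like
cells. The raw fraction cannot support such a cutoff — it moves in steps of
1/k and is inflated toward the simulated pool share everywhere.

Two design facts follow from the construction. Total-count normalization
means doublets are recognized by hybrid expression profiles, not size
(genuine cells vary strongly in size anyway); consequently doublets of two
same-population cells are undetectable in principle, a limitation shared by
all simulation-based detectors. And inside `apply_qc_filters` the score is
computed on the cells that survive the trim and MAD steps: simulating
doublets from debris barcodes would place artificial doublets inside the
clean-cell cloud and corrupt the ranking.

### Size factors and normalization

Size factors are median-of-ratios against the per-gene mean over genes
detected in at least half the cells, falling back to total-count scaling
when fewer than 100 such genes exist; factors are rescaled to mean 1.
The pooled-deconvolution estimator of the cited workflow is replaced by
this simpler estimator with the identical contract (positive per-cell
scalings, mean 1). Normalized expression is log2(count/factor + 1).

## Clustering and annotation

Cells are embedded by PCA (economy SVD, deterministic) of the centered
log-normalized matrix — deliberately without gene scaling or
highly-variable-gene selection, matching the minimal published recipe — and
connected to their k = 15 Euclidean nearest neighbors (undirected union
graph). Communities are found by Leiden modularity optimization
(RB-configuration, resolution 1.0, seeded); labels are relabeled
contiguously from 1 in order of first appearance.

Annotation correlates every cell (Spearman) against two reference panels —
an immune panel and a whole-organism atlas panel — over the 500
most-variable shared reference genes per panel; the best correlation across
panels wins, with lexicographic tie-breaks. The arbitration between the two
references is not specified in the source workflow; best-correlation-wins
is the default and an `immune_first` strategy is provided.

Composition shifts between two conditions use a two-sided Fisher's exact
test per cluster on the 2×2 membership table, Benjamini–Hochberg corrected
across the clusters of one comparison. The `direction` call is relative to
the second condition (enriched = larger share there at FDR ≤ 0.05).

## Differential expression

The published edgeR-based genewise NB GLM/LRT machinery is replaced by a
two-group NB likelihood-ratio test tailored to the one-vs-rest contrast the
pipeline actually performs:

* dispersion α per gene by method of moments on size-factor-scaled counts
  (variance μ + αμ²), floored at 1e-8 and shrunk 30% toward the global
  median;
* group means by maximum likelihood at fixed dispersion with per-cell
  exposures, solved by the fixed-point iteration
  μ ← Σy / Σ[(y+r)s/(r+sμ)] (r = 1/α), the rearranged score equation,
  iterated to 1e-14 relative tolerance from the Poisson start;
* LRT = 2(ℓ_alt − ℓ_null) against χ² with one degree of freedom, clipped at
  zero; BH across genes;
* log2FC = log2((μ_a+ε)/(μ_b+ε)) with ε = 1e-8, "group of interest over
  rest".

Swapping the groups negates log2FC and preserves p-values to 1e-12. The
LRT is validated against a grid-search likelihood maximization in the
tests. Marker selection takes the top 25 upregulated genes per cluster
(ranked by p, then |log2FC|, then gene id) and drops any gene appearing in
more than one cluster's list (the uniqueness rule).

## Signature derivation and scoring

The cross-species signature is the set of homolog pairs passing
log2FC ≥ 1.5 (up) or ≤ −1.5 (down) in both species; an FDR ≤ 0.05 gate is
applied by default (configurable, including off), mirroring the
fold-change-plus-FDR filtering used elsewhere in the same workflow, since
the signature-defining sentence prints only the fold-change cutoffs.
Output is ordered by cross-species mean |log2FC|, descending.

Per-cell scoring is raw detection (count > 0) — the fraction of signature
genes detected, computed separately for the up and the down set. Whether
the original per-cell maps used raw detection or a normalized threshold is
not stated; raw detection follows the wording "detected genes".

Cohort scoring z-transforms each signature gene across samples (sample
standard deviation, n−1; a population-sd variant is available), multiplies
down-gene z-scores by −1, and averages with equal weights. Scores are
invariant to per-gene affine rescalings, which is why the choice of
upstream bulk normalization (total-count scaling here) is immaterial to the
score. The median splits samples into low (score ≤ median) and high groups;
assigning the median element to the low group reproduces a 223/222 split of
445 distinct scores.

## Survival statistics

Kaplan–Meier is the standard product-limit estimator (censoring ties at an
event time remain at risk for it). The two-group comparison uses the
log-rank chi-square (df = 1) and a single-covariate Cox partial likelihood
with Efron tie correction, solved by damped Newton iterations to
|Δβ| < 1e-8; monotone likelihoods (complete separation) are capped at
|β| = 15 with a warning. The test behind the published survival p-value and
the hazard-ratio estimator are unnamed in the source; log-rank and Cox are
the standard companions of a KM comparison. All three routines are
cross-checked against lifelines in the tests, and the Cox estimate is
verified to satisfy its score equation to 1e-6. The group-difference t-test
defaults to Welch (unequal variances), matching the spreadsheet "type 3"
convention; an equal-variance variant is available.

Comparisons of the two KM curves are made on the shared follow-up range
(event times up to the shorter group's maximum observation): beyond a
group's last observation its KM value is an extrapolated plateau and
dominance is not meaningful there.

## Synthetic data: what it emulates, and what it does not

`generate_sc_dataset` draws NB counts (gamma-Poisson, variance μ + αμ²,
α = 0.3) over 5000 genes with log-normal gene-level baselines (median 0.4
counts/cell). Three clusters of 200 cells carry 30 private marker genes
each (log2FC 2) and RNA-content scales geomspace(0.7, 1.6) — real cell
types differ in library size, and the resulting flat-topped composite QC
metrics are what keeps the MAD rules from biting the genuine population.
Per-cell sizes are gamma with CV 0.15. The planted tumor-specific cluster
additionally carries 21 up / 9 down signature genes at |log2FC| = 2 with
tight well-expressed baselines (6× and 16× the global median — markers are
never barely-detected genes, and repression is only measurable from a high
baseline). Mitochondrial genes (prefixed `mt-`) carry ~5% of healthy
counts. 55% of barcodes are debris: binomially thinned to 15% of their
parent counts with 30% of the remainder reassigned to mito genes —
emulating the debris-dominated totals distribution that the trim rule
presupposes, with the debris mode (~500 counts) falling in the rule's ×2
branch. 5% doublets are element-wise sums of two distinct parents that
remain in the matrix.

At these defaults (measured over generator seeds 0–11): the QC stage
recovers ≥ 96% of planted bad cells while removing ≤ 2.6% of clean cells;
Leiden recovers exactly 3 clusters at ARI ≥ 0.93 on clean kept cells; DE
recovers all planted signature genes at the published thresholds.

Not simulated: ambient RNA contamination, batch effects, UMI collisions,
gene-gene correlation within cells, spliced/unspliced layers, and
cluster-specific dispersion. Passing tests on these data therefore show
the *procedures* behave as specified under their assumed statistical
structure, not that the thresholds are optimal for any particular real
dataset.

`generate_cohort` draws standard-normal expression per gene (100 mutant /
211 wild-type samples by default), shifts mutant samples by ±1 on the
signature genes, and draws exponential survival with hazard
baseline × HR^z (HR 2.0 per standardized score unit, baseline 0.05).
Censored samples (30%) have their time replaced by a uniform draw on
(0, T), which keeps the marginal censoring fraction at the configured rate.

## Degenerate inputs and tie-breaks

Constant total-count vectors return their value as the mode; MAD = 0 flags
exactly the values different from the median; all-zero cells have
pct_mito = 0; removing every cell is a reported warning, not an error; an
empty high group after a degenerate median split warns; annotation ties
break lexicographically; marker ranking ties break by p, then |log2FC|,
then gene id; the tumor-volume helper swaps length/width with a warning
when given in the wrong order (the greatest diameter is the length by
definition).
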