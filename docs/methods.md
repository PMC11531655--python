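# Methods

`regulonpipe` reimplements, at desk scale, a regulon-centric analysis of
two-condition glioma transcriptomics: gene-regulatory-network (GRN)
inference from single cells, AUCell regulon activity, connection-
specificity-index (CSI) module discovery, a regulon-derived signature
for consensus subtyping of a bulk survival cohort, and a multi-
algorithm survival-model grid. Because the original cohorts are
restricted-access, every stage is exercised on synthetic data whose
planted structure the pipeline must recover; this note documents the
models, the defaults and the reasoning behind the open design choices.

## Synthetic single-cell model

Counts are negative binomial with mean `μ` and dispersion `θ`
(variance `μ + μ²/θ`, default `θ = 2`), sampled through the
gamma–Poisson mixture, then zeroed with uniform Bernoulli dropout.
The latent structure, per cell:

* Each of the `n_modules` (default 4) TF modules draws a shared latent
  `L_m = mean_m(condition) + N(0, icc)`. One module ("the shifted
  module") has `mean = activity_shift` (default 1.5) in the WT
  condition and 0 in MUT; all other module means are 0.
* A TF's activity is `a = L_m + N(0, 1 − icc)` — unit total variance
  with within-module intraclass correlation `module_icc = 0.5`. The
  split is what makes modules co-active (CSI can find them) while
  leaving enough TF-specific signal for edge attribution; with
  independent TF activities the module structure would be invisible,
  and with fully shared activity the regulons would be
  indistinguishable.
* The TF's own transcript has baseline 2 counts and reads out its
  activity with unit gain (`μ_tf = 2·e^a`) — the co-expression
  assumption every transcript-based GRN method makes. Each planted
  target has `μ = b·e^{w·a}` with gene baseline `b` log-normal and
  per-edge weight `w ~ U(0.5, 1.5)`.
* Background genes carry a heavy-tailed (housekeeping-like) baseline so
  library size is dominated by constitutive expression. Without this,
  half the transcriptome responds to module activity, library-size
  normalisation couples background genes to the TFs, and spurious edges
  swamp the ranking — an artefact of an unrealistically concentrated
  transcriptome, not of the method.
* Cell types (8, glioma-tissue proportions) are defined by the marker
  panel used for annotation; markers are modelled as near-exclusive
  (off-type baseline 0.25 counts, in-type ×40), as canonical markers
  are.

Default dropout is 0.2 on top of the NB zeros (total sparsity ≈ 50–70%
depending on the gene). With heavier dropout the two-marker cell types
cannot be recovered per cell at the generator's documented accuracy
regardless of marker strength, so 0.2 is the default that keeps every
planted structure recoverable while staying in the droplet-data range.

What the generator does **not** emulate: batch effects, doublets,
ambient RNA, expression-dependent dropout, cell-cycle structure, and
spatial coordinates. Passing tests therefore demonstrate that the
implementation recovers the structures it models under realistic count
noise — not that it is robust to every artefact of real droplet data.

## Synthetic bulk cohort

Expression is Gaussian on a log-like scale. Two planted subtypes split
the cohort; the `n_signature_genes` (default 10) signature genes are
shifted by `subtype_sep` SDs (default 2) in subtype 1. Survival is
exponential with hazard `h0·exp(lp − mean(lp))`, where
`lp = β·Σ x_signature` (default `β = 1`) and `h0 = ln2/24` anchors
median survival at 24 months for an average patient. Censoring is
independent exponential; its rate is solved (Brent root-finding on
`E[c/(c+h_i)]`) so the expected censored fraction equals
`censor_rate`, exactly even when hazards vary by orders of magnitude.
When generated after the single-cell analysis, the signature pool can
be set to the analysis-selected regulon's targets, tying the cohort's
prognostic signal to the regulon stage the way the original study's
IRF7-regulon signature drives its subtypes.

## QC, normalisation, annotation

Cells are kept when `min_genes ≤ detected ≤ max_genes` (defaults
200/7000) and the ribosomal fraction (RPS*/RPL* prefix; the community
convention, since no explicit gene list is standard) is strictly below
5%. Mitochondrial filtering is deliberately omitted. Normalisation is
library-size scaling to 10⁴ followed by `log1p`. HVGs are ranked by
variance/mean dispersion of the log values, standardised within up to
20 equal-frequency mean bins (bins are widened so each holds ≥ 5 genes;
a degenerate bin falls back to centred dispersion); ties break by gene
symbol, making the selection deterministic. Annotation scores each cell
type as the mean normalised expression of its markers and takes the
argmax, ties to the earlier type in the table.

## Meta-cells and GRN inference

Meta-cells are k-means clusters (k-means++ with fixed seed, 3 restarts)
in 20-PC PCA space of the log-normalised HVG matrix, defaulting to 10
cells per meta-cell. Profiles are pseudo-bulk: arithmetic means of the
raw member counts, library-normalised and log-transformed before
inference. Pseudo-bulk aggregation roughly halves the readout noise of
a mean-of-log profile and is what makes weak edges detectable.

Edge scoring (default `method="forward"`) regresses each non-TF gene on
the TF profiles by greedy forward selection, crediting each selected TF
with the ΔR² at its inclusion. This attribution rule is the crux:
co-active TFs are *collectively* informative about the shared module
latent but *individually* redundant, so methods that spread credit
(boosted stumps' split-gain shares, ridge coefficients) dilute the true
TF's importance below the noise of co-active siblings. Greedy ΔR²
instead awards the entire shared signal to the best single readout —
almost always the true regulator. A second pass repeats the attribution
with *metagene* readouts: each TF's profile plus its top-5 first-pass
targets, weighted by their gains, which denoises the activity estimate
(a single low-expressed transcript is a poor readout); a target being
scored is left out of any metagene containing it so no edge matches
itself. Selection stops after 8 steps or when ΔR² < 0.01 (≈ 3× the
null maximal-correlation gain at 300 meta-cells). A gradient-boosted-
stump scorer (split-gain share × out-of-bag explained gain) and a
|Spearman| share screen (correlations under 2 standard errors zeroed)
are retained as alternatives; on planted data their edge rankings reach
PR-AUC ≈ 0.4 and ≈ 0.4 respectively versus ≈ 0.95 for the default,
which is why the default deviates from the GRNBoost2-style scorer.

Regulon assembly keeps an edge iff the prior table (the motif-database
stand-in) lists the pair, orders targets by descending importance, and
drops regulons under `min_regulon_size = 10`.

## Regulon activity (AUCell) and group tests

For a regulon and a cell, genes are ranked by descending expression
(ties broken stably by input gene order, which only matters in the
zero-inflated tail); the recovery curve counts regulon genes within the
top `k` ranks for `k = 1..K`, `K = floor(top_frac·n_genes)` with
`top_frac = 0.05` (the AUCell convention). RAS is the exact
cumulative-sum area under this curve divided by the maximal area — no
trapezoids, so results are reproducible to machine precision and lie in
[0, 1]. Being rank-based, RAS is invariant to monotone transforms of a
cell's expression. Group-specific regulons use one-way ANOVA on RAS
with Benjamini–Hochberg correction; groups under 3 cells are dropped.

## CSI modules

With `r` the Pearson correlation matrix of RAS rows,
`CSI(i,j) = |{k ≠ i,j : r(i,k) < r(i,j) − δ and r(j,k) < r(i,j) − δ}| / (N−2)`,
strict inequalities, margin `δ = 0.05` (the published CSI convention;
no formula is standard), diagonal 1. Modules are flat clusters of the
CSI row vectors under Ward linkage with Euclidean distance, cut at
height 8 — the height scale implies Euclidean-space heights, not a
1−CSI metric, and at the default 50-regulon scale the planted modules
separate far above this cut while within-module merges stay far below.
Module ids are M1..Mk by first appearance along the dendrogram leaves.
Module activity is the unweighted mean RAS of members, with
per-condition means and the WT−MUT contrast reported per module.

## Differential expression, signature, subtyping

DE between two groups is the two-sided Wilcoxon rank-sum per gene
(robust, standard for expression; no parametric assumption on log
counts) with BH adjustment; `logFC` is the difference of group means of
log-scale values. The filtered view applies `adj_p < 0.05` and
`|logFC| > 1` (a flag restricts to positive logFC only). The signature
is the intersection of a regulon's genes (targets + TF) with the
DE-passing set.

Consensus clustering subsamples 80% of samples and 80% of features
`n_resamples` times per k (k-means base learner, per-resample seeds
drawn from one generator), accumulates co-assignment frequencies among
co-sampled pairs, and derives final labels by average-linkage
clustering of 1−consensus. k is chosen by the largest relative
delta-area of the consensus CDF (area at k = 2, relative gains above),
reported and overridable — the criterion is known to favour small k on
clean data, which is exactly the planted regime.

## Survival prognosis

Univariate Cox screening fits each gene by Newton iterations on the
Efron partial likelihood (covariate standardised internally; tolerance
1e-8 on the step, max 50 iterations; constant or non-converging genes
skipped). The model-input gene set is the three-way intersection of
screened genes, subtype-DE genes, and the signature.

The model grid crosses feature selectors {none, lasso-Cox, forward
stepwise Cox by AIC, RSF permutation importance} with final models
{random survival forest, lasso-Cox, ridge-Cox, elastic-net-Cox
(α = 0.5), stepwise Cox, componentwise gradient boosting}, minus the
three selector/model pairs that duplicate an algorithm. Selector
results are cached per selector. Penalised-Cox strength is chosen by
5-fold cross-validated C-index on the training cohort only; RSF uses
500 trees, log-rank splitting and a fixed seed; trained models are
frozen for external validation (no refitting on test cohorts).
Harrell's C is computed from its pairwise definition (comparable pair:
earlier time has an event; score ties count ½). Risk groups split at
the *training* median score; evaluation reports Kaplan–Meier tables,
the log-rank test, and cumulative/dynamic time-dependent ROC AUC at
12–60 months with inverse-probability-of-censoring weights from the KM
censoring estimator (scikit-survival), horizons outside a cohort's
follow-up range skipped.

## Numerical and degenerate-input choices

* All randomness flows from explicit integer seeds; k-means and
  resampling seeds are derived deterministically from them.
* Constant RAS rows get correlation 0 (logged) rather than NaN;
  numerically negative F statistics from identical groups are clamped
  to 0 with p = 1.
* Duplicate gene symbols are collapsed by summation on read, with a
  warning.
* File writers emit fixed row/column order; the run manifest excludes
  the output path, so identical seeds yield byte-identical artifact
  checksums.
* A preranked gene set with no misses (the whole universe) has ES = 0;
  sets intersecting the data below `min_size = 3` are skipped.

## Problem sizes

The default synthetic study uses 3,000 cells (1,500 per condition),
2,000 genes, 50 TFs × 20 targets in 4 modules, 300 meta-cells, and
bulk cohorts of 120–400 samples — sizes at which every planted
structure is comfortably identifiable and a full end-to-end run takes
well under a minute on one core. Test and acceptance runs use these or
smaller sizes.

## Known limitations

* The GRN stage assumes TF transcript abundance tracks TF activity;
  post-transcriptionally regulated TFs violate this in real data and
  would be missed, as in all co-expression GRN methods.
* The motif prior is an input table; no motif scanning or enrichment
  scoring is performed.
* The consensus-clustering k criterion is reported, not enforced as
  truth; on real data k should be inspected alongside the CDF curves.
* ssGSEA (not GSVA's kernel variant) is the implemented single-sample
  statistic.
* The grid covers 21 selector × model combinations as a registry;
  additional algorithms plug in but are not provided.
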