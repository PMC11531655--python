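# regulonpipe

Regulon-centric analysis of two-condition glioma transcriptomics:
gene-regulatory-network inference, AUCell regulon activity, connection-
specificity-index (CSI) module discovery, regulon-signature consensus
subtyping, and a multi-algorithm survival-prognosis grid — driven end
to end by a synthetic-data generator that plants every structure the
analysis assumes.

## The problem

IDH (isocitrate dehydrogenase) mutation status is the central molecular
classifier of diffuse glioma: wild-type tumours behave far more
aggressively than mutant ones. A regulon-level view asks which
transcription factors (TFs) drive that difference: a **regulon** is a
TF plus its inferred target genes, its per-cell **activity** (RAS) is
the AUCell statistic

```
RAS(regulon, cell) = area under the recovery curve of regulon genes
                     within the top 5% of the cell's expression ranking,
                     normalised to [0, 1]
```

and regulons whose activities co-vary *specifically* with each other —
measured by the connection specificity index

```
CSI(i, j) = #{k ≠ i,j : r(i,k) < r(i,j) − δ  and  r(j,k) < r(i,j) − δ} / (N − 2)
```

— form modules whose mean activity can be contrasted between IDH
wild-type (WT) and mutant (MUT) cells. The condition-responsive module
yields a signature (regulon genes ∩ differentially expressed genes)
used to find patient subtypes by consensus clustering, and the
intersection of subtype genes, DE genes and univariate-Cox prognostic
genes feeds a grid of survival models (random survival forest,
penalised Cox variants, stepwise Cox, componentwise boosting × feature
selectors) ranked by Harrell's C-index on held-out cohorts.

The original cohorts are restricted-access, so the package ships a
first-class synthetic generator (`regulonpipe.synthetic`) producing
NB-with-dropout single-cell counts with planted cell types, regulons,
co-active modules and a condition shift, plus bulk survival cohorts
with planted subtypes and a known log-hazard signature — every
downstream claim is tested against this planted truth. It is intended
for methodologists who want a transparent, fully seeded reimplementation
of this analysis style with its assumptions spelled out and testable.

## Worked example

```python
from regulonpipe.config import PipelineConfig
from regulonpipe.pipeline import run_pipeline

report = run_pipeline(PipelineConfig(outdir="out", seed=0,
                                     sim_seed_sc=1, sim_seed_bulk=2))
print(report)
```

prints (about 30 s on one core):

```
{'n_modules': 4, 'top_module': 'M1', 'top_regulon': 'TF001',
 'signature_size': 5, 'selected_k': 2,
 'subtype_logrank_p': 3.8251739985006225e-51,
 'best_model': 'stepwise+rsf',
 'best_cindex_train': 0.8812221077926536,
 'best_cindex_test': {'test1': 0.8062825725903442,
                      'test2': 0.694777758999493}}
```

Reading this: CSI clustering of the 50 inferred regulons cut at height
8 yields 4 modules; module M1 — the one planted with a WT activity
shift — shows the largest |WT − MUT| mean-activity difference, and its
most condition-responsive regulon (TF001) intersected with the
condition DE genes gives a 5-gene signature. Consensus clustering of
the bulk cohort on that signature selects k = 2 subtypes whose survival
separates (log-rank p ≈ 4e-51). The model grid picks a stepwise-
selected random survival forest, with Harrell's C of 0.88 on the
training cohort and 0.81/0.69 on the two held-out cohorts. Per-stage
artifacts (QC table, edge list, regulon JSON, RAS matrix, CSI matrix,
module assignments, DE table, consensus matrices, leaderboard, risk
scores) are written to `out/` with deterministic contents.

The same pipeline is available from the shell:

```
regulonpipe run-all --outdir out --seed 0
```

with per-stage subcommands (`simulate`, `qc`, `grn`, `activity`,
`modules`, `subtype`, `prognosis`) for running stages on your own
MTX/CSV, GMT and prior-table inputs.

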