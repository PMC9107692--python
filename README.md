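# lumipipe

Molecular risk scoring, intrinsic subtyping and IHC-surrogate analysis for
HR+/HER2− early-stage breast cancer profiled with a 72-gene targeted RNA-seq
panel (50 tumor genes, 17 immune genes, 5 housekeeping genes).

Most hormone-receptor-positive, HER2-negative stage 1 breast cancers are
luminal and do well on endocrine therapy alone, but a small minority are
molecularly basal-like or HER2-enriched and relapse early. Expression assays
that find them (nearest-centroid intrinsic subtyping, multi-gene recurrence
scores) are often unavailable in routine pathology, so surrogate rules built
from immunohistochemistry (ER, PR, Ki-67, basal markers) are used instead.
This package implements the full analysis chain that compares those
approaches, for pathologists and biostatisticians working with targeted-panel
counts:

- **`expression_qc`** — count ingest, sample QC (keep samples with < 30 %
  zero-count genes and > 10,000 total reads), CPM → log2(x+1) → gene-median
  centering → per-gene standardization;
- **`molecular_scoring`** — nearest-centroid intrinsic subtype
  (LumA/LumB/HER2E/Basal) by Spearman correlation ρₖ over the 50 tumor genes;
  the proliferation-weighted risk of recurrence
  `ROR-P = Σₖ wₖ ρₖ + w_P · P` (P = mean centered expression of an 11-gene
  proliferation set), rescaled to 0–100 and classed low/medium/high at 29/53;
  the 21-gene recurrence score RS from housekeeping-referenced group scores
  (HER2, ER, proliferation, invasion + CD68/GSTM1/BAG1) with the published
  floors and the affine 0–100 map, classed at 18/31; a 17-gene immune score
  (min–max 0–100, "istrong" iff score ≥ cutoff, preset 45.5);
- **`ihc_subtyping`** — the > 1 % staining positivity rule, the St. Gallen
  LumA/LumB split (LumB iff PR < 20 % or Ki-67 > 30 %), the modified surrogate
  that first tests *basal-like = any basal marker positive ∧ Ki-67 ≥ 40 % ∧
  ER ≤ 10 %*, and TILs dichotomization (high iff > 13.5 %);
- **`cohort_analysis`** — Youden-index ROC cutpoints, cross-tabulation with
  Cohen's κ, Kaplan–Meier/log-rank, uni-/multivariate Cox with
  Benjamini–Hochberg FDR;
- **`synthetic_cohort`** — a generator of cohorts with known ground truth
  (subtype-structured negative-binomial counts, IHC channels coupled to the
  expression latents, exponential proportional-hazards survival), plus the 12
  published basal-marker-positive reference cases as a packaged fixture;
- **`lumipipe` CLI** — `simulate`, `qc`, `score`, `surrogate`, `analyze`,
  `all` subcommands over a YAML config.

## Worked example

```python
from lumipipe.pipeline import RunConfig, run_all

summary = run_all(RunConfig(outdir="demo", seed=3, n_patients=87))
print(summary["subtype_counts"])            # {'LumA': 60, 'LumB': 16, 'Basal': 11}
print(summary["ror_class_counts"])          # {'medium': 63, 'high': 19, 'low': 5}
print(round(summary["kappa_ror_vs_rs"], 3)) # 0.28
print(round(summary["concordance_modified_ihc_vs_molecular"], 3))  # 0.908
```

This simulates an 87-patient cohort, runs QC and normalization, trains
centroids on the cohort's true labels, scores every sample (subtype, ROR-P,
RS, immune score), applies the IHC surrogate rules, and writes the per-stage
CSVs plus `demo/summary.json`. The printed numbers say: most samples are
luminal A; ROR-P puts 19 samples in the high-risk class; agreement between the
ROR-P and RS risk classes is weak (κ = 0.28) while the modified IHC surrogate
agrees with the molecular subtype for 90.8 % of samples.

Running the modified basal rule on the packaged published cases:

```python
from lumipipe.synthetic_cohort import fixture_as_clinical
from lumipipe.ihc_subtyping import surrogate_table

calls = surrogate_table(fixture_as_clinical())
print(sorted(calls.index[calls["modified"] == "Basal"]))  # [1, 2, 3, 4, 5, 6]
```

The rule recovers exactly the six molecularly basal-like cases among the 12
marker-positive ones.

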