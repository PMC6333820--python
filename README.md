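# progmir

Integrative miRNA/mRNA meta-analysis for progressive disease, modelled on
the multi-cohort study design used to chart pancreatic-cancer progression
(healthy controls → chronic pancreatitis → carcinoma → metastatic disease).

The package is for computational biologists who have several expression
datasets spanning an ordered disease spectrum — typically miRNA profiles
from tissue and blood plus one mRNA cohort — and want to find the small set
of regulators whose loss tracks progression, the target genes they release,
and whether those molecules stratify survival.

## What it computes

1. **Per-dataset differential expression** with an empirical-Bayes
   moderated t. Each feature is tested between a disease group and HC;
   sample variances s² (d residual df) are shrunk toward an
   inverse-chi-square prior (d₀, s₀²) fitted by method of moments on the
   log variances:

       s̃² = (d₀·s₀² + d·s²) / (d₀ + d),   t = logFC / √(s̃²(1/nₐ + 1/n_b))

   with d₀ + d degrees of freedom. miRNAs are called at raw p < 0.05;
   mRNAs at BH-adjusted p < 0.05 and |FC| ≥ 1.5.
2. **Cross-dataset meta-signatures**: features called with a consistent
   direction in at least k of the datasets for a contrast (default k = 2
   of 3), intersected across the CP and PDAC contrasts to isolate the
   progression-wide signature.
3. **Progressive genes**: group means strictly monotone along the stage
   order with terminal logFC above a threshold (default 1.5), plus a
   Kohonen self-organizing map partitioning of samples.
4. **Counter-regulation**: validated miRNA→gene pairs where a
   meta-significant miRNA and a DE target gene move in opposite
   directions — the signature of miRNA-mediated repression.
5. **Target-set enrichment**: weighted Kolmogorov–Smirnov GSEA. The
   enrichment score is the signed extremum of a running sum that gains
   |score|^w/Σ|score|^w at set members and loses 1/(N−N_hit) elsewhere;
   nominal p comes from a seeded permutation null (default 1000
   permutations, add-one within the same-signed tail). A hypergeometric
   over-representation test covers pathway/TF collections supplied as GMT.
6. **Survival analysis**: rank-based stratification (median, top quartile
   vs rest, or upper vs lower quartile), Kaplan–Meier curves, the
   log-rank test, a univariate Cox proportional-hazards fit
   (Newton–Raphson on the Breslow partial likelihood), multi-gene
   mean-z signatures, and Wilcoxon group comparisons for marker
   validation.

A synthetic-cohort generator (`progmir.synthetic`) plants counter-regulated
miRNA→gene modules whose effects grow with stage, decoy interactions, and
survival outcomes tied to planted genes through a proportional-hazards
model, so every stage of the pipeline can be scored against ground truth.

## Worked example

```python
from progmir import pipeline, synthetic
from progmir.synthetic import SimConfig

cfg = SimConfig(seed=1, n_genes=800, n_mirnas=250, targets_per_mirna=25)
studies, interactions, truth = synthetic.generate_cohort(cfg)
survival = synthetic.generate_survival(studies[-1], truth, cfg)
report = pipeline.run_pipeline(
    pipeline.PipelineConfig(seed=1), mirna_studies=studies[:3],
    mrna_study=studies[-1], interactions=interactions,
    survival_table=survival)

common = report.tables["meta_signature_common"]
print(f"CP/PDAC-common meta-signature: {len(common)} miRNAs")
print(report.tables["mirna_ranking"].head(3).round(4).to_string())
print(f"hub miRNA in truth: {truth.hub_module.mirna_id}")
comb = report.tables["survival_combined"].iloc[0]
print(f"combined 15-gene signature: HR={comb['hr']:.2f}, "
      f"log-rank p={comb['logrank_p']:.2e}")
```

which prints:

```
CP/PDAC-common meta-signature: 6 miRNAs
          gsea_p_pdac  es_pdac  abs_es_pdac  targets_cp  targets_pdac  target_growth
mirna_id
miR-0172        0.001   0.9334       0.9334          31            38              7
miR-0003        0.001   0.8658       0.8658          16            25              9
miR-0205        0.001   0.8542       0.8542          12            25             13
hub miRNA in truth: miR-0172
combined 15-gene signature: HR=7.20, log-rank p=4.86e-12
```

All five planted miRNAs land in the CP∩PDAC meta-signature (one null
feature slips in at the nominal false-positive rate); the planted "hub"
regulator — the module with the most targets and steepest stage
schedule — tops the ranking by GSEA significance and enrichment
magnitude; and the mean-z score over the 15 survival-linked genes splits
the cohort into strata with a hazard ratio of 7.2.

The same stages are scriptable from the shell:

```bash
progmir simulate --out fixtures/ --seed 1
progmir normalize --in fixtures/mirna_1_expression.tsv \
    --ann fixtures/mirna_1_annotations.tsv --out z.tsv
progmir de --in fixtures/mirna_1_expression.tsv \
    --ann fixtures/mirna_1_annotations.tsv --contrast HC:PDAC --out de.tsv
progmir integrate --fixtures fixtures/ --out results/ --seed 1
progmir run --config config.yaml --out results/
```

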