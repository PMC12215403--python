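# famtrait

Predicting a binary stress-resistance trait from gene-family copy numbers
across a species phylogeny — and explaining the predictions gene by gene,
species by species.

## The problem

Comparative screens grow hundreds of microbial species under a stressor
(here: an oxidative agent at 0/1/2 mM, OD600 read hourly for a week),
summarise each species by its relative growth — the empirical area under
the growth curve (EAUC) under stress divided by the untreated control — and
ask which gene families explain why some species resist and others do not.
`famtrait` implements that entire analysis as a tested, deterministic
pipeline:

1. **Phenotyping** — plate-reader CSVs → per-replicate EAUC ratios →
   per-species relative growth (`famtrait.growth`).
2. **Labelling** — the dual-dose tail rule: the worst-growing 20% at the
   low dose are *sensitive* (class 0), the best-growing 20% at the high
   dose are *resistant* (class 1); with 285 species this yields 57 + 57 =
   114 labelled instances (`famtrait.traits`).
3. **Classification** — a native random forest (bagged CART, Gini splits)
   over orthogroup copy-number features with top-50 Gini-importance feature
   selection, grid search, balanced 10% holdout, 10-fold stratified CV, and
   replicated evaluation: AUC-ROC, AUC-PR, F1, mean balanced confusion
   matrix, mean ROC band (`famtrait.forest`, `famtrait.evaluate`).
4. **Attribution** — exact path-dependent TreeSHAP: for every species,
   per-family Shapley values on the probability scale satisfying
   base + Σφ = prediction to 1e-9, verified against 2^m coalition
   enumeration (`famtrait.shapley`).
5. **Phylogenetic association** — PGLS with Brownian covariance
   (β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y; V from shared branch lengths) relating family
   size to growth across all screened species, plus iTOL annotation export
   (`famtrait.phylo`).
6. **Enrichment** — one-sided hypergeometric over-representation of the
   selected families' genes against a custom background with BH FDR
   (`famtrait.enrich`).
7. **Ground truth** — a synthetic-study generator (Yule tree, birth–death
   copy-number evolution, liability-model trait, logistic growth curves)
   so every stage is testable with known causal families
   (`famtrait.simulate`).

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data with known ground truth (all outputs regenerate from seed 1):

```sh
python analysis/01_simulate_study.py        # 285 species, 2,000 families
python analysis/02_phenotypes_and_classes.py
python analysis/03_train_and_evaluate.py    # 10 replicates, 200-tree grid
python analysis/04_explain_predictions.py
python analysis/05_phylogenetic_association.py
python analysis/06_enrichment.py
python analysis/07_null_control.py
```

Selected output (seed 1):

```
57 sensitive + 57 resistant = 114 instances
phenotype cutoffs: sensitive <= 0.175 at 1 mM, resistant >= 0.829 at 2 mM

10 replicates
  validation: AUC-ROC 0.970  AUC-PR 0.970  F1 0.897
  test:       AUC-ROC 0.986  AUC-PR 0.985  F1 0.928
causal families in the selected top 50: 4/5

explained 114 species; max local-accuracy error 2.22e-16
highest-impact families (mean |SHAP|):
OG0000662    0.0713
OG0001035    0.0615
OG0000723    0.0532
copy-number vs SHAP correlation: {'OG0000662': 0.923, 'OG0000723': 0.904,
                                  'OG0001035': 0.853, 'OG0001223': 0.918}
top family OG0000662: minimal separating copy number = 4

OG0000662: PGLS slope +0.0888 (p=3.95e-12, R=+0.396)
causal_term  k=15  K=17  fold_enrichment 14.6  FDR 5.9e-16
```

Reading this: the tail rule reproduces the 114-instance arithmetic exactly;
the classifier separates the classes strongly because the planted causal
families (liability weights 1.0–0.7 per gene copy) dominate the signal —
four of the five reach the top-50 importances in this replicate (the fifth
carries the weakest weight), and the three highest-impact families by mean
|SHAP| are all causal. Every species' prediction decomposes exactly into
per-family Shapley contributions; more copies of a causal family push a
species toward the resistant class (φ–count correlation ≈ 0.9), with
species at ≥ 4 copies of the top family uniformly pushed positive. The
phylogenetically corrected regression confirms the copy-number/growth
association across all 285 species, and the planted causal annotation term
enriches 14.6-fold. The null control (`07`) re-runs everything on studies
with no causal signal: held-out test AUC collapses to ~0.5, while
validation AUC stays optimistic by construction (feature selection precedes
CV — see `docs/methods.md`).

`analysis/08_reproduce_published_matrix.py` runs the same protocol on a
real 114 × 72,380 orthogroup instance matrix if you supply one on disk.

A `famtrait` CLI wraps the same library surface
(`famtrait simulate|phenotype|classify|train|explain|pgls|enrich|run-all`).

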