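# Methods

`famtrait` predicts a binary stress-resistance trait from gene-family copy
numbers across a species phylogeny and interprets the predictions gene by
gene and species by species. This note documents the models, the numerical
choices, and what the synthetic validation does and does not demonstrate.

## Phenotype: empirical AUC ratios

Growth is summarised by the empirical area under the OD600 curve (EAUC), a
trapezoidal integral over the raw time grid in OD·h — no parametric logistic
fit is involved, so the statistic is exact on piecewise-linear curves and
indifferent to lag-phase shape. Resistance at dose *d* is the per-replicate
ratio EAUC(d) / EAUC(0), with treated and control wells paired by species and
replicate, averaged over replicates. Replicates whose control shows no
growth (EAUC = 0) are excluded with a warning rather than propagating NaNs.
Integration uses the actual timestamps of each curve; curves on different
grids are integrated each on its own grid before taking the ratio. Baseline
subtraction (`od − od[0]`, clipped at 0) is available but off by default, so
the default statistic is the plain area ratio.

## Classes: the dual-dose tail rule

Species are labelled by extremes: the floor(f·N) poorest growers at the low
dose become class 0 (sensitive) and the floor(f·N) best growers at the high
dose become class 1 (resistant); everything between stays unlabelled and is
kept only for the copy-number/growth correlations across all screened
species. With N = 285 and f = 0.2 this gives 57 + 57 = 114 instances. Ties
at a cutoff are broken by a stable (value, species) sort, so the labelling
is order-independent and reproducible. A species qualifying for both tails
means the rule is degenerate for that dataset and is raised as an error, not
resolved silently — silent precedence would corrupt labels.

## Classifier: native random forest

The forest is implemented in the package (bagged CART trees, Gini split
criterion, per-node uniform feature subsampling, leaf class fractions)
rather than delegated, because the trained trees are also the substrate of
the exact Shapley computation and of the importance bookkeeping, which need
full access to node sample counts. Design constants: bootstrap of n draws
with replacement per tree; minimum leaf size 1; split thresholds at
midpoints of consecutive distinct sorted values; left branch takes values ≤
threshold; tie-breaks by lowest feature index then lowest threshold, so
training is deterministic given the seed (single-threaded by contract; an
established implementation is used in the test suite only as a correlation
sanity check). Gini importance is the sample-weighted impurity decrease
summed over each tree's internal nodes, averaged over trees and normalised
to sum to 1; feature-selection ties are broken by family identifier.

The evaluation protocol per replicate r (seed = base_seed + r): a balanced
holdout of round(holdout_frac·N/2) species per class; the remaining species
shuffled and dealt round-robin per class into k stratified folds; top-`n`
families selected by the importance of a forest fit on the training
partition only; a full grid search over {n_estimators, max_depth,
max_features} scored by mean CV F1 (ties prefer fewer trees, then shallower);
validation metrics from the pooled out-of-fold predictions of the winning
cell (per-fold AUC is also reported); test metrics from a final fit on the
whole training partition. Confusion matrices are row-normalised (per true
class) before averaging across replicates — that is the sense in which the
mean confusion matrix is "balanced". The mean ROC band interpolates each
replicate's step ROC onto a fixed FPR grid (0, 0.01, …, 1) before averaging.

One property of this protocol deserves emphasis: feature selection runs
once per replicate on the full training partition, *before* the
cross-validation loop. Validation scores therefore carry selection optimism
— with ~2,000 candidate families and ~100 training species, selecting the 50
chance-best features pushes null out-of-fold AUC well above 0.5 (~0.7 in our
null studies). That ordering is deliberate (it mirrors the screening
protocol this package models) and is why the held-out test partition, which
selection never sees, is the readout used for the no-signal control. The
holdout is likewise excluded from feature selection, the defensible reading
of an otherwise ambiguous ordering.

## Attribution: exact path-dependent TreeSHAP

Coalition values are path-dependent conditional expectations: descending a
tree, a feature in the coalition follows the instance's branch, a feature
outside it averages both children weighted by training sample counts.
Shapley values are computed exactly by the polynomial-time extend/unwind
recursion over weighted feature paths; per-tree attributions are averaged
over the forest (the model output is the tree mean) and the base value is
the training-weighted mean leaf value averaged over trees. Outputs are on
the probability scale (class-1 leaf fractions), positive values pushing
toward the resistant class. Correctness is established against a 2^m
brute-force enumeration of the classic Shapley formula (models restricted to
≤ 20 used features), and local accuracy — base value plus attributions
equals the predicted probability — is asserted to 1e-9 for every explained
instance. Attributions use the training-distribution (path-dependent)
expectations, not interventional ones with a background dataset; that is the
classic Tree Explainer behaviour for this model family. When a report
aggregates SHAP across training replicates it says so; per-replicate
matrices are retained.

## Association: PGLS under Brownian motion

The copy-number/growth association is generalized least squares with error
covariance V[i,j] = shared root-to-MRCA path length (the Brownian-motion
covariance; Pagel's λ fixed at 1 — λ estimation is out of scope and
recorded as an open question). Estimation is by Cholesky whitening:
β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y, σ̂² = RSS_V/(n−2), two-sided t test on n−2 df. The
reported "phylogenetically adjusted" correlation is R = sign(β₁)·√(1 −
RSS_V/TSS_V) with TSS_V from the V-weighted intercept-only fit — a
definition this package declares, since figure-level "R" conventions vary.
On a star phylogeny with equal branch lengths the whole machinery reduces
exactly to OLS, which the tests exploit. Non-ultrametric trees are accepted
as-is; a singular V (zero-length cherries) raises with a suggestion to
jitter branch lengths. Pruning collapses unary nodes and sums their branch
lengths, preserving all tip-to-tip path lengths.

## Enrichment: custom-background over-representation

The gene universe is the reference species' genes present in the orthogroup
matrix, not its whole genome — enrichment is relative to what the dataset
could have selected. Per term: one-sided upper-tail hypergeometric p
(two-sided Fisher available behind a flag), fold enrichment (k/n)/(K/N),
Benjamini–Hochberg FDR across all tested terms, then filtering (default
min 5 genes, FDR < 0.001). Annotations are flat term→gene tables; ontology
ancestors are not propagated — pre-propagate if hierarchical closure is
wanted.

## Synthetic studies: what they emulate

The generator produces a complete, cross-consistent study from one seed:

* **Phylogeny** — a Yule (pure-birth) tree scaled to unit depth, root
  splitting at time zero; all rates below are per unit tree height.
* **Neutral families (default 1,995 of 2,000)** — root count Geometric on
  {0, 1, ...} (mean 1), then a linear birth–death copy process along each
  branch (duplication = loss = 0.5). Branch transitions are sampled from the
  process's exact law (per-copy extinction probability plus geometric
  offspring, composed as Binomial + NegativeBinomial), which is equivalent
  to event-by-event simulation but vectorises across families. The result
  is a sparse, zero-inflated, heavy-tailed integer matrix like real
  orthogroup tables, with phylogenetically autocorrelated counts.
* **Causal families (default 5)** — a birth–death–innovation process:
  per-copy duplication 0.5 and loss 3.0 plus constant gain 7.5, giving a
  mean-reverting copy number around 3 (ancestry forgotten at rate
  loss − dup = 2.5 per unit depth), simulated exactly event-by-event. Fast
  turnover is the realistic dynamics for the reductase/transporter-like
  families such screens implicate, and it is also what makes recovery
  well-posed: a trait driven by slowly evolving families is phylogenetically
  confounded — under a pure duplication–loss causal process (whose tip
  covariance is BM-like at any rate), dozens of neutral clade-marker
  families carry as much class information as the causal ones, and no
  feature selector can be expected to distinguish them.
* **Trait** — liability L = Σ w_c·count_c + σ_phylo·BM + σ_iid·ε with
  default weights (1.0, 1.0, 0.9, 0.8, 0.7), σ_phylo = 0.5, σ_iid = 0.25;
  true resistance r = logistic(L − median L). All noise draws are recorded
  in the truth file, so liability is reproducible from the outputs.
* **Growth curves** — hourly logistic OD curves over 168 h, N0 = 0.05,
  K0 = 1.0, per-species growth rate U(0.05, 0.15)/h with per-(species,
  replicate) lognormal jitter (σ = 0.05) shared across doses (paired
  plates), carrying capacity under dose d of K0·logistic(6·(r − 0.35·d)) so
  EAUC responds monotonically to r at both 1 and 2 mM, and multiplicative
  lognormal reading noise (σ = 0.02). Three replicates at doses 0/1/2 mM.

What the synthetic validation does **not** show: performance on real
orthogroup matrices (72,380 families, genuine LD-like correlation structure,
annotation noise), robustness to plate artefacts (edge effects, evaporation,
non-logistic kinetics), or behaviour when causal families are themselves
strongly phylogenetically structured — in that regime the pipeline finds
clade markers instead, which is a property of the inference problem, not of
the implementation.

The **null control** sets all causal weights to zero *and* σ_phylo to zero.
With heritable (Brownian) liability noise alone the trait is still
phylogenetically structured and clade-marker families genuinely predict it
(null AUC ≈ 0.9); pure iid liability is the only signal-free condition, and
under it held-out test AUC sits at chance.

## Problem sizes and reproducibility

Default synthetic studies run at the full design scale (285 species, 2,000
families). The bundled analysis drivers and the acceptance script use 10
training replicates with 200-tree forests (a 500-tree / 100-replicate run
is one flag away in `analysis/03_train_and_evaluate.py --full`); the
feature-selection forest uses 200 trees. Every stochastic step draws from
named substreams of a single seed (SeedSequence spawning per stage and per
tree) with fixed traversal orders, so datasets, fitted models, and reports
are bit-reproducible per seed, single-threaded.

Open questions resolved as declared package choices (not claims about any
external protocol): pooled out-of-fold predictions are the default
validation AUC (per-fold means also reported); SHAP may be aggregated
across replicates when stated; BH is the FDR procedure; the enrichment test
is one-sided over-representation.
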