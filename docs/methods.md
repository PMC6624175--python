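# Methods

## Model and pipeline

The package treats transcriptional regulation as a set of depth-1 trees:
one transcription factor (TF) root with target-gene leaves, each leaf
weighted by a regulatory interaction score (RIS) and the whole module
signed as activated (targets positively correlated with the TF) or
repressed (negatively correlated). The pipeline's claim is not that the
inferred edges are causal, but that the *enrichment of a module's target
program in a sample* — summarized per sample by ssGSEA — is a useful,
interpretable feature space in which contexts (subtypes, cell types)
separate, and that mean-decrease-impurity importance of those features
identifies which programs define each context.

Assumptions worth keeping in mind:

* TF activity is proxied by TF mRNA level; post-transcriptional
  regulation is invisible to this model.
* Module signs come from marginal Pearson correlation over *all* samples;
  module construction is deliberately independent of the context labels,
  so the ranking stage cannot leak label information through the modules.
* ssGSEA scores depend on expression only through within-sample ranks, so
  any monotone per-sample normalization of the input leaves the RMES
  matrix unchanged.

## Stage-by-stage choices

### Network inference (`grn_inference`)

Per-target stochastic gradient boosting: `n_rounds` ≤ 500 depth-3 stumps,
learning rate 0.01, row subsampling 0.9, early stop once the rolling mean
(window 25) of out-of-bag improvement is non-positive. These mirror the
published configuration of the boosting family of network inference
methods; equivalence to any particular implementation is at the contract
level only (non-negative per-model-normalized importances, determinism,
recovery of planted regulators). The edge weight is each TF's share of
total impurity-reduction gain summed over all boosting rounds, normalized
per target model; a constant target yields an all-zero row rather than an
error. Each target model is seeded by `crc32(seed:target)`, making the
edge list independent of per-target scheduling and safe to parallelize.

A second backend (per-target extremely randomized trees, `backend="etr"`)
satisfies the same contract. It is kept as an option, not the default:
without early stopping it is no faster at the reference scale, and its
uniform feature sampling spreads credit across correlated TFs, admitting
more borrowed-target edges than boosting does.

### Module assembly (`module_builder`)

Defaults `min_ris = 0.001`, `top_k_per_tf = 50`, `rho_min = 0.03`,
`min_targets = 5`, following the module-construction conventions of the
regulon-analysis family; all are exposed on the CLI. Ties in the top-k
filter break by target symbol so results are reproducible. Motif-based
target pruning is external to this package: a pruning hook accepts a
(tf, target, keep) table produced by any motif-enrichment tool and is
applied after assembly, preserving the pipeline shape without shipping
multi-gigabyte motif databases.

### Enrichment scoring (`ssgsea`)

Rank scores are N…1 along the descending-expression ordering, ties broken
by gene symbol. The exponent α defaults to 0.25, the convention of the
single-sample GSEA literature. The scored set is the module's targets
only — the TF names the module but is not a member, since the module is
scored as the regulated program (a flag on the module set construction
can include it). NES normalization divides all raw scores by the global
range (max − min) of the raw matrix, so the NES matrix has range exactly
1 whenever two raw scores differ; an all-equal raw matrix (possible only
in degenerate single-cell toy inputs) maps to zeros with a warning rather
than dividing by zero.

### Importance ranking (`importance_ranking`)

The forests are scikit-learn `RandomForestClassifier(n_estimators=500,
criterion="gini")` with standard bootstrap resampling and √K feature
subsampling; the FIS computation is done in this package by extracting
every fitted tree into an explicit node structure and accumulating
(Sₙ/S)·ΔGini(n) per feature, averaged over trees. S is interpreted as the
per-tree training-sample count (the bootstrap size = number of labeled
samples), the standard mean-decrease-impurity weighting. FIS is *not*
re-normalized to sum to 1 across features — the raw average is reported —
so values are comparable across contexts of one run but not across runs
with different tree counts. Ranking ties (which occur at FIS = 0) break
lexicographically by module id. Equal group means map to down-regulated.
Samples present in the RMES matrix but absent from the label table are
scored but excluded from ranking and evaluation.

### Evaluation (`evaluation`)

Precision = tp/(tp+fp), recall = tp/(tp+fn), F1 = 2PR/(P+R), all defined
as 0 when tp = 0. (One published presentation of these formulas prints
"true negatives" in the recall denominator; that is treated here as a
typo for the standard form — the accompanying claim that an
always-negative classifier has F1 = 0 holds either way.) Folds are
stratified by default and metrics are computed on out-of-fold predictions
pooled over the k folds, the more common convention; per-fold averaging
is not offered. The dominant-class baseline predicts, per training fold,
the most frequent class (multiclass) or the majority binary class
(one-vs-rest; ties go to the negative class). When no class holds a
binary majority its one-vs-rest accuracy for class c is exactly
(S − S_c)/S with F1 = 0; when a class exceeds half the cohort the
baseline predicts positive for it and the formula switches to S_c/S. The
default classifier for the feature-based modes is an L1-regularized
linear SVM (`LinearSVC(penalty="l1", dual=False)`, one-vs-rest) with no
feature standardization; any scikit-learn-style estimator factory can be
passed as `classifier_spec` — the classifier is a harness component, not
part of the scientific core.

## Synthetic cohorts (`synthdata`)

Expression is generated on a latent Gaussian log2 scale (base mean 5, TF
sd 1) and mapped through 2^z − 1 (clipped at 0), i.e. marginally
log-normal and non-negative, so the pipeline's log2(x+1) preprocessing
recovers the latent scale almost exactly. Each TF is a pure activator or
pure repressor (alternating), giving exactly one true module per TF and
making "planted module" unambiguous; targets are
base + (±β)(z_TF − base) + N(0, noise_sd). Planted TFs get a
`context_shift` added to their latent mean in their assigned context, so
an activator's module is up-regulated there and a repressor's module
down-regulated. The reference geometry is 3 contexts × 60 samples, 10 TFs
× 20 targets, 300 noise genes, β = 1, noise sd 0.3, shift 2, two planted
TFs per context — sized so a full pipeline run takes ~20 s on one CPU and
a 20-seed recovery experiment finishes in minutes.

What the generator deliberately does **not** emulate: realistic marginal
count distributions, library-size or batch effects, TF–TF combinatorial
regulation, or motif structure. Passing the recovery tests therefore
shows the pipeline's machinery is correct and sensitive at realistic
effect sizes, not that it will rank true regulons first in any given real
cohort.

A known interaction worth documenting: two TFs planted in the *same*
context share that context's shift and are therefore correlated across
the cohort, so the inference stage genuinely sees each planted TF as a
weak predictor of the other's targets. Boosting attributes almost all
gain to the true regulator and such borrowed-target modules stay small
and low-ranked; backends that split credit more uniformly (ETR) make them
more prominent. This mirrors the real-data behavior of
correlated-regulator artifacts and is why the boosting backend is the
default.

## Numerical notes

* Enrichment scores are computed vectorized (cumulative sums along the
  ranked list); the test suite checks them against a literal O(N·|set|)
  double-loop summation to 1e-9 on 200 random instances.
* FIS from tree traversal is checked against an independent per-feature
  scan to 1e-12 on random (not greedily grown, hence possibly
  negative-ΔGini) forests; non-negativity is asserted only for fitted
  forests, where greedy Gini splitting guarantees it.
* Gini input validation requires probabilities summing to 1 within 1e-9.
* All randomness flows from explicit integer seeds; identical inputs and
  seeds give identical artifacts, byte for byte.

## Limitations

* No motif-enrichment pruning is bundled; the hook expects external
  verdicts.
* FIS carries no significance estimate; ranks are descriptive.
* The RIS threshold defaults are heuristics; with them, module counts on
  real cohorts depend strongly on cohort size and depth of sequencing,
  and published module counts cannot be reproduced exactly without the
  original thresholds.
* The linear-SVM evaluation harness reports pooled-fold metrics only.
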