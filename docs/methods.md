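# Methods

`conet` implements a multi-stage co-expression network analysis for
prioritizing tissue-specific drug targets: per-condition co-expression
networks (CNs), random-walk community detection with key-cluster selection,
overlays of physical regulatory and protein-interaction networks with
permutation nulls, random-forest scoring of TF co-binding, projection of
co-expression onto metabolic reactions with Fisher-Z differential
clustering, and a hub-gene neighborhood pipeline ending in quartile-
stratified differential expression. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
benchmark does and does not establish.

## Co-expression networks

Expression is consumed as TPM (genes x samples); RPKM input is rescaled per
sample, `TPM_gs = RPKM_gs / sum_g RPKM_gs * 1e6`, so every sample column
sums to one million. Before correlation, the lowest-expressed third of
genes (by mean across samples; ties broken by gene id) is dropped —
low-abundance genes contribute mostly technical noise to Pearson r. All
unordered gene pairs are then scored by Pearson correlation; genes with
zero variance are excluded up front because a NaN row would poison the
quantile cutoff. The CN keeps the top 1% of pairs by *signed* r
(`ceil(0.01 * P)` edges exactly, boundary ties broken by r then
lexicographic pair id). Signed rather than absolute ranking is the default
because a strongly positive empirical cutoff is what a co-expression edge
is meant to capture; an `absolute` flag exists for sensitivity analysis.
Whether to correlate raw or log2(x+1) values is left to the caller; the
log scale is used here as a robustness re-ranking for tumor cohorts, whose
heavy-tailed expression can let a few samples dominate raw-scale r.
Per-condition gene filtering implies per-condition edge counts; a fixed
shared pair universe can be emulated by filtering a common gene list
upstream.

## Communities, key clusters, and the cluster graph

Communities are detected with the random-walk (walktrap) agglomeration of
Pons & Latapy as implemented in igraph (walk length 4, the reference
default; cut at maximum modularity), relabelled deterministically by each
cluster's smallest member id. Each cluster is summarized by the mean local
clustering coefficient of its members computed on the *induced*
intra-cluster subgraph (nodes of degree < 2 contribute 0); a flag switches
to full-graph local coefficients, and node-averaging (not transitivity) is
the default reading of "clustering coefficient". The top `ceil(K/2)`
clusters by coefficient are flagged *key* (ties: size, then id) — the most
internally co-expressed half of the partition.

The cluster-level graph uses a configuration-model expectation: for
clusters A and B, `E_AB = (sum_{a in A} k_a)(sum_{b in B} k_b) / (2N)` with
k the full-network degree and N the total edge count; A and B are linked
iff the observed inter-cluster edge count satisfies `O_AB >= 2 * E_AB` and
`O_AB > 0`. Edge conservation (`sum O_AB + within-cluster edges = N`) is
asserted in tests. Gene-set enrichment of key-cluster members is an
upper-tail hypergeometric test, `p = P[X >= k]`, against flat GMT term
sets; use-site alphas follow the analysis (0.01 tissue-specific genes,
1e-4 GO, 0.05 TF binding, 0.01 subsystems).

## Physical-network overlays

Regulatory (TF -> target) and protein-interaction edge lists are scored by
the mean Pearson r of their mappable gene pairs. Significance comes from an
endpoint-resampling permutation null: each of 1,000 permutations redraws
both endpoints of every edge uniformly from the actual network's node set
(self-loops and duplicate pairs rejected, edge count preserved; collisions
with original edges are allowed and their rate logged). The empirical
p-value uses the add-one rule `(1 + #{null >= obs}) / (1 + n_perm)` and is
never zero. Endpoint resampling (rather than degree-preserving rewiring)
matches the "permuted among genes of the actual network" design; a
degree-preserving variant is a possible sensitivity analysis but is not the
default.

Co-regulated pairs are gene pairs sharing TF binding (RN) or interaction
partners (PPIN; the pair members themselves are excluded from the shared
set). The top 0.1% of co-regulated pairs by shared-regulator count and the
zero-count stratum are the contrast groups; mean co-expression as a
function of the count floor yields the co-regulation curve, which is
monotone non-decreasing under the additive-TF generative model (see
below). Individual regulators are selected when their linked pairs' r
values differ from all evaluated pairs (two-sided two-sample KS, p < 0.05
— the background is the full correlation table, not just network pairs)
and |mean r| > 0.1; regulators with fewer than 3 mappable pairs are
skipped.

## TF importance

The co-binding feature matrix has one row per top-1% co-expressed pair and
one binary column per TF (1 iff the TF binds both genes); the response is
the pair's r. All-zero columns are dropped and reported; dropped TFs are
reappended with importance 0 so the table scores every TF. A regression
random forest (500 trees, sqrt-feature subsampling, fixed seed) supplies
impurity (variance-reduction) importance by default; held-out permutation
importance is available because impurity importance is biased for
correlated binary features. Forest hyperparameters are this package's
choices — the analysis design does not pin them — and are recorded in
output metadata. The top `ceil(0.01 * T)` TFs are flagged most influential.

## Reaction clusters

Reaction co-expression is the max-over-enzymes projection:
`r_max(R1, R2) = max_{e1 in R1, e2 in R2} r(e1, e2)`; reactions with no
expressed enzyme are excluded and listed. The max (not mean) reflects that
one co-regulated isozyme pair suffices to couple two reactions.
Agglomerative clustering on distance `1 - r_max` with average linkage
(single/complete by flag; linkage was an open choice) is cut to exactly k
clusters — k = 100 at the scale of a genome-wide metabolic model, k = 20
at this package's synthetic desk scale (~150 reactions), keeping cluster
sizes comparable. Reactions are processed in sorted-id order, so the
clustering is independent of input order.

Per cluster and condition, co-expression is summarized as the mean Fisher
Z (z = atanh(r), r clamped to |r| <= 1 - 1e-7) over within-cluster
reaction pairs; the clustering is frozen on the reference condition and
reused for all comparisons. The difference `z_ref - z_other` ranks
clusters; the top `ceil(0.01 * k)` per comparison are flagged
condition-specific (vs tissues) or disease-deregulated (vs tumor), and a
cluster flagged in the disease comparison plus at least one tissue
comparison is the combined candidate class. TF-binding enrichment per
cluster is hypergeometric over the enzyme-gene universe of clustered
reactions (regulation is asked about within the metabolic gene space, not
the whole genome); a cluster is *highly regulated* when its enriched TFs'
importance scores are stochastically greater than the full score
distribution (one-sided two-sample KS, p < 0.25, at least 2 scored TFs —
the permissive alpha mirrors the screening intent of this step).
Subsystem enrichment is hypergeometric over clustered reactions.

## Hub-gene targets

For a focal hub gene, candidates are genes with mean expression > 1 TPM
("mean over samples" is this package's reading; configurable); the top-n
by r with the hub forms the per-condition neighborhood. The robust set is
the intersection of the raw-scale and log-scale top lists of the focal
condition. A candidate is kept when it appears in the top lists of fewer
than 3 conditions — the focal condition counts, so a strictly focal gene
has count 1, and a gene present in exactly 3 conditions is removed — and
carries a user-supplied tissue-enriched annotation (GMT); without an
annotation the count criterion applies alone, with a warning. The
neighborhood size is scaled with the universe: 100 genes against a
>10,000-gene transcriptome, 10 against the ~115-gene synthetic hub
universe, keeping the list a comparable (small) fraction so that chance
membership does not swamp the condition-count filter.

Count cohorts are split at the hub-expression quartiles with group size
`round(n/4)` (0.5 rounds up), reproducing 371 -> 93 + 93. Differential
expression between the groups is a self-contained negative-binomial Wald
test: median-of-ratios size factors; per-gene pooled method-of-moments
dispersion `alpha = (var - mu) / mu^2` from within-group normalized
counts, floored at 1e-8; delta-method standard error for the log fold
change `Var(log FC) = (1/mu_1 + alpha)/n_1 + (1/mu_2 + alpha)/n_2`;
two-sided normal p-values with Benjamini-Hochberg adjustment. All-zero
genes receive p = 1 and a flag. Equivalence with DESeq-family shrinkage
estimators is not claimed; the implementation is validated by simulation
calibration (type-I error <= 0.07 at nominal 0.05, >= 95% power for
4-fold changes at n = 93 vs 93, dispersion 0.1) and cross-checked against
DESeq2 on a small fixture, where the significant sets coincide.

## Synthetic data

The generator emulates the study conditions at desk scale. Defaults: 400
genes plus 33 TF genes, 4 conditions (three tissues, one disease cohort),
120 samples each, 4 planted modules of 30 genes at latent correlation
rho = 0.8, 3 causal TFs (effect w = 2.0, 15 targets each from a shared
background pool so multi-TF sharing occurs) among 30 decoys, a PPIN at
density 0.02 with half its edges within modules, 150 reactions in 6
subsystems, a 5 + 5 specific/ubiquitous hub-partner design, and
negative-binomial counts (dispersion 0.1) with 5% of genes at 4-fold
planted changes, half up, half down.

Module members follow a one-factor model `x = sqrt(rho) f_m +
sqrt(1 - rho) eps` per condition, so the within-module latent correlation
is exactly rho. Causal-TF targets receive the TF's factor additively with
weight w and are rescaled to unit variance, giving a pair sharing k TFs a
latent correlation `k w^2 / (1 + k w^2)` — strictly increasing in k, which
makes the co-regulation curve's monotonicity an analytic property rather
than an empirical accident. The first module loses its factor in the
disease condition (the planted deregulation); the planted metabolic
subsystem draws its enzymes from that module, and a second subsystem draws
enzymes from the causal-TF target pool so one reaction cluster is
genuinely TF-governed. Causal TFs are expressed genes (their expression is
the factor itself); decoy TFs are expressed noise whose binding targets
are drawn from genes outside planted modules and the causal pool —
otherwise a decoy that happened to bind two same-module genes would carry
real co-binding signal and the causal/decoy ground truth would be
ill-posed. Latent values map to positive TPM-like values by the fixed
monotone transform `exp(b_g + 0.7 x)` with per-gene baselines
`b_g ~ N(log 50, 1)`; Pearson r on the emitted scale is therefore mildly
attenuated relative to rho (log-scale correlation recovers it exactly),
so recovery tests assert rank/latent structure with tolerance. Counts are
NB with `var = mu + alpha mu^2` and mild lognormal depth variation. Each
generator draws from its own RNG stream spawned from the master seed, so
adding or rerunning one generator never perturbs another, and identical
seeds give bit-identical output.

What the synthetic benchmark does *not* establish: behavior under
batch effects, isoform-level structure, realistic read-level noise,
correlated module overlap, or GTEx/TCGA-scale multiple-testing burdens.
Passing the planted-structure tests shows the statistics recover the
structures they are defined to find at realistic effect sizes; it does not
certify performance on real cohorts.

## Problem sizes and reproduction

`scripts/acceptance.py --seed N --out results/acceptance.json` recomputes
the headline quantities from scratch: the 371-sample quartile split,
community ARI (rho = 0.8, 200 samples), the disease-deregulated reaction
cluster detection rate over 60 replicate studies, causal-TF importance
AUC, the co-regulation co-expression gain, the regulatory-network
permutation p, hub-partner recall/precision, null calibration of the
permutation and KS gates (100 replicates each), and NB power/type-I error
at n = 93 vs 93. These sizes keep a full run within a couple of minutes on
one CPU; the test suite uses the same sizes with fixed seeds.

## Known limitations

- The per-gene NB dispersion is method-of-moments without shrinkage;
  at very small n (< ~10 per group) the Wald test will be anti-conservative
  relative to DESeq-style moderation.
- Impurity importance inherits the known bias toward features with more
  splits; with binary co-binding features this mostly cancels, but the
  permutation option is preferable when feature prevalences differ widely.
- Endpoint-resampling nulls do not preserve degree sequences; hub-heavy
  physical networks can inflate the null spread slightly.
- The walktrap cut at maximum modularity inherits modularity's resolution
  limit; very small planted modules may merge at low sample sizes.
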