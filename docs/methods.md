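# Methods

## Overview

`psntopo` implements a graph-based dimension-reduction strategy for
predicting binary clinical outcomes from omics profiles in the
"small n, large p" regime. Instead of feeding thousands of expression
features to a classifier, the pipeline:

1. screens features against the outcome with a two-sample Wilcoxon rank-sum
   test on training samples only;
2. builds a **patient similarity network (PSN)** — a fully connected
   weighted graph whose nodes are patients and whose edge weights are
   soft-thresholded Pearson correlations of their (selected) profiles;
3. replaces each patient's profile with **graph-topological features**:
   twelve centralities and, optionally, binary module-membership
   indicators;
4. trains small multilayer perceptrons (and SVM / random-forest baselines)
   on these features, scored by balanced accuracy (bACC).

Because the topological feature space has a fixed dimension and meaning
(twelve centralities) regardless of the measurement platform and the
original feature count, a model trained on one cohort can be applied to
topological features extracted from another cohort — the basis of the
cross-platform transfer harness.

An important subtlety of the PSN is that it is **transductive**: the graph
is built over all samples of a cohort (training and test patients together),
because centralities are only meaningful relative to the whole cohort.
Outcome labels never enter the graph construction, so no label leakage
occurs; feature *selection*, by contrast, is strictly training-only.

## PSN construction

Patient profiles are compared with Pearson correlation; the signed WGCNA
transform rescales correlations to weights:

    s_ij = (1 + r_ij) / 2,      a_ij = s_ij ** beta  in (0, 1].

A pair with r = −1 is mapped to 1e-12 instead of 0 so that the graph stays
literally fully connected. The power `beta` is the smallest integer in
1..20 whose weighted degree distribution is approximately scale-free:
R² ≥ 0.8 for the regression of log10(bin frequency) on log10(mean degree)
over 10 equal-width degree bins (empty bins dropped; fewer than three
non-empty bins is flagged degenerate). If no power reaches the target, the
best-fitting power is used. Binning equal-width in raw k (the
`scaleFreeFitIndex` convention of the WGCNA package) was chosen over
equal-width bins in log10(k) after the former proved markedly more stable
on synthetic cohorts; the fit table returned by `soft_threshold_power`
records R², slope and degree summaries for every candidate power.

## Centralities

The twelve per-patient metrics are: weighted degree, closeness,
current-flow closeness, current-flow betweenness, eigenvector, Katz, HITS
(hub), PageRank, load, weighted local clustering coefficient, and the two
peeling ("iterative") variants of weighted degree and clustering.

Conventions, where a choice had to be made:

- similarity weights are used directly by the eigenvector family and as
  conductances by the current-flow metrics; shortest-path metrics
  (closeness, load) use distances d = 1/a;
- the clustering coefficient is the Onnela geometric-mean form with weights
  normalized by the maximum weight of the (sub)graph;
- HITS hub and authority scores coincide on an undirected graph; the hub
  score is reported;
- iterative solvers use power iteration with tolerance 1e-10 and at most
  10,000 iterations; Katz attenuation is 0.9/λ_max, PageRank damping 0.85;
- the peeling metrics repeatedly compute the base metric on the surviving
  subgraph, record the maximum node's score and remove it; ties (exact for
  the symmetric cliques that arise at the end of the peel) are broken by
  lowest node index within a 1e-9 relative tolerance, so the order is
  invariant to floating-point evaluation order.

Every metric is checked in the test suite against an independent
definition-level brute-force oracle (explicit Floyd–Warshall, grounded
Laplacian solves per source/target pair, dense eigendecompositions, scalar
peeling) on 100+ random weighted graphs with n ≤ 6, at tolerance 1e-8.

## Modules

Two module detectors provide the binary membership features:

- **Spectral**: normalized-Laplacian embedding, module count k ∈ [2, 15]
  chosen by the largest eigengap, seeded k-means on the row-normalized
  eigenvector matrix.
- **Weighted SBM**: edge weights are modelled as Gaussian with block-pair
  means and a pooled variance; the block count B minimizes a
  description-length objective (−2 log-likelihood + BIC parameter penalty +
  a label-coding term 2·n·H(block proportions)). The label-coding term is
  essential: without it, greedy label search always shaves residual
  variance and plain BIC overfits B on structureless graphs. The fit uses a
  spectral k-means initialization followed by greedy single-node
  reassignment with incremental sufficient-statistics updates; the search
  over B stops after three consecutive non-improvements, and
  `objective_trace` records the objective of every candidate evaluated.

Module features are one-hot indicators. They are cohort-specific (module
identities do not align across cohorts), so the transfer harness refuses
them and transfers centralities only.

## Classifiers

The DNN is a numpy multilayer perceptron: 1–4 hidden ReLU layers with
2/4/8 units, softmax output, cross-entropy loss with per-sample class
weights (w_c ∝ 1/freq_c, normalized to mean weight 1), inverted dropout on
hidden layers (grid 0.15–0.40), mini-batches of 32, 1000 epochs with an
evaluation-set bACC computed every 10 epochs. Optimizers: adam
(β₁=0.9, β₂=0.999), adadelta (ρ=0.95), adagrad (accumulator initialized at
0.1), and proximal adagrad (adagrad with optional L1/L2 shrinkage, reducing
to adagrad when both are 0). Learning rates span 1e-4 to 5e-2. The
checkpoint with the best evaluation bACC is kept by default (`checkpoint=
"final"` is available). At the capped learning rate adadelta converges much
more slowly than the others; this is inherent to its update rule, not a
defect.

The architecture grid enumerates non-increasing width sequences by default
(34 architectures over depths 1–4), with the unconstrained variant
(120 sequences) available — both enumerations are exposed because the
boundary between them is a modelling convention, not a mathematical fact.

SVM (linear/RBF, cost and gamma on the 2^(2p) grid, p ∈ [−4, 4]) and random
forests (100–10,000 trees) are fitted with scikit-learn under identical
class weighting. SVM is deterministic and runs once per grid point; DNN and
RF are stochastic and run 10 replicates with seeds derived from a master
seed via `SeedSequence`.

The 50/25/25 train/evaluation/validation split uses per-class
largest-remainder rounding subject to the global partition sizes, which
reproduces 249/125/124 on 498 samples and keeps every partition's class
proportions within one sample of the cohort prevalence. Classes with fewer
than two samples are rejected; a two-sample class may legitimately be
absent from one of the two test partitions.

## Evaluation and transfer

Balanced accuracy is the mean of the two per-class recalls. Model groups
are compared with one-way ANOVA followed by Tukey HSD (significance
threshold 0.01; pairwise mean differences Δ_bACC reported with 95% Tukey
confidence intervals).

`external_validate` applies a frozen model to another cohort's centrality
features, aligning columns by metric name. The external cohort's features
are z-scored **on that cohort** by default: each cohort auto-selects its
own soft-threshold power, so raw centrality magnitudes live on
cohort-specific scales, and reusing the training cohort's scaler collapses
transfer to chance whenever the two cohorts pick different powers (observed
directly on synthetic platform pairs: bACC 0.25–0.50 frozen vs ~0.95
re-standardized). The frozen-scaler variant remains available
(`restandardize=False`). A parameter hash asserts that scoring never
mutates the model.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes,
with defaults chosen once to mirror a realistic single-disease cohort:

| parameter | default | meaning |
|---|---|---|
| n_samples | 200 | patients per cohort |
| n_features | 2000 | measured features (genes/transcripts) |
| n_informative | 100 | features whose mean shifts with the outcome |
| effect_size | 1.0 | standardized shift, in units of noise_sd |
| class_prevalence | 0.2 | 4:1 imbalance (1/3 models the 2:1 outcome) |
| n_blocks | 10 | co-expression blocks (shared latent factor each) |
| block_rho | 0.6 | within-block feature correlation |
| noise_sd | 1.0 | idiosyncratic noise scale |
| sample_scale_sd | 1.2 | lognormal σ of the per-sample signal scale |

Each feature is class shift (± effect, random sign per feature) + its
block's latent factor (scaled per sample) + Gaussian noise. Labels are
drawn to match prevalence exactly. The per-sample lognormal scale on the
block-factor component models sample-level heterogeneity in global signal
strength (tumour purity, RNA quality): high-scale samples correlate with
many others and become hubs, which is precisely what gives the
soft-thresholded degree distribution its heavy tail. Without such
heterogeneity the PSN of an equicorrelated cohort has no hubs and no power
makes it scale-free. The class shift is deliberately *not* scaled per
sample, so separability is preserved (a class-weighted ridge classifier on
raw features reaches bACC > 0.9 held-out at effect_size 1).

Platform pairs share one latent matrix; view B applies a per-feature
distortion — affine (positive scale + offset) or rank-monotone (strictly
increasing cubic) — plus independent measurement noise (default sd half
the cohort noise). This reproduces the property the transfer design needs
(similar patient-correlation structure across views, mean absolute
difference < 0.2) without attempting realistic microarray or RNA-seq
marginal distributions (no count models, no probe effects, no batch
structure). Passing tests on these cohorts therefore demonstrates the
machinery and its contracts, not performance on real data.

## Problem sizes and numerical notes

Tests and the acceptance script run cohorts of n = 200 and p = 2000 with
grids of a few architectures × 10 replicates — large enough to exercise
every code path and the statistical properties, small enough to run on one
CPU in minutes. Degenerate inputs are handled explicitly: constant
profiles are a hard error naming the sample; an all-equal correlation
matrix short-circuits power selection to β = 1 with a warning flag; a
degree distribution with fewer than three non-empty bins yields a flagged
NaN fit; constant feature columns are dropped (with a count) at
standardization; features constant across both classes get Wilcoxon P = 1.

## Known limitations

- The Gaussian weighted SBM is a pragmatic block model for dense similarity
  graphs, not a degree-corrected Bernoulli/Poisson SBM; on sparse graphs a
  dedicated implementation would be preferable.
- The iterative (peeling) centralities follow the score-at-removal reading;
  the base-metric strategy is pluggable but alternative readings (e.g.
  rank-at-removal) are not implemented.
- No topological overlap matrix, network fusion, survival endpoints, or
  graph-convolutional models.
- Wilcoxon screening applies no multiple-testing correction by design (raw
  P < 0.05 with a top-5% fallback); it is a recall-oriented screen, not an
  inferential procedure.
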