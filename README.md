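# psntopo

Patient-similarity-network topology features for clinical outcome
prediction.

Omics cohorts are "small n, large p": a few hundred patients described by
tens of thousands of expression features. `psntopo` implements a
graph-based dimension-reduction strategy for this regime: profiles are
screened with a Wilcoxon rank-sum test, the retained features define a
fully connected **patient similarity network** (PSN; nodes = patients,
edge weights = soft-thresholded Pearson correlations, the WGCNA power β
chosen by the scale-free criterion R² ≥ 0.8), and each patient is then
represented by **twelve graph centralities** (weighted degree, closeness,
current-flow closeness/betweenness, eigenvector, Katz, HITS, PageRank,
load, clustering coefficient, and iterative "peeling" variants of degree
and clustering) plus optional binary module-membership features from
spectral clustering and a weighted stochastic block model. Small deep
neural networks (1–4 ReLU layers of 2–8 units) are trained on these
features against SVM and random-forest baselines, scored by balanced
accuracy

    bACC = (sensitivity + specificity) / 2,

with stratified 50/25/25 train/evaluation/validation splits, class weights
inversely proportional to class frequencies, seeded replicates, and
ANOVA + Tukey comparisons of model groups (p < 0.01, Δ_bACC with 95% CIs).

Because the centrality space has fixed dimension and meaning regardless of
the original measurement platform, a trained model can be applied to
topological features extracted from an entirely different cohort — the
package ships this cross-platform transfer harness, along with a seeded
synthetic-cohort generator (paired "platform views" included) so the whole
pipeline is testable without any external data.

Intended users: computational biologists and methods researchers working
on outcome prediction from transcriptomics (or any omics profile that
supports a meaningful patient-patient correlation).

## Worked example

```python
import numpy as np
from psntopo import *
from psntopo.synthetic import OUTCOME_NAME

cfg = CohortConfig(effect_size=1.5, seed=11)      # 200 patients, 4:1 classes
expr, outcomes = generate_cohort(cfg)
y = outcomes.labels(OUTCOME_NAME)
split = stratified_split(outcomes, OUTCOME_NAME, seed=11)

X = expr.profiles()                                # samples x features
train_mask = np.isin(expr.sample_ids, split.train_ids)
sel = select_features(wilcoxon_pvalues(X[train_mask], y[train_mask]))

graph = build_psn(X[:, sel.selected], expr.sample_ids)   # transductive PSN
cent = compute_centralities(graph)
feats = standardize(assemble_features([(cent, "syn")], "centralities"))

grid = [DnnSpec(hidden_sizes=h, learning_rate=lr)
        for h in ((8, 4), (8, 8, 8, 2)) for lr in (1e-3, 5e-3)]
records = grid_search("dnn", feats, y, split, grid,
                      replicates=10, master_seed=11)
best = best_model(records)
print(f"PSN: beta={graph.beta:.0f}, scale-free fit R2={graph.fit_r2:.3f}")
print(f"selected {sel.selected.size} features -> {feats.d} centralities")
print(f"best DNN: {best.config}")
print(f"validation bACC = {best.bacc:.3f}")
```

Output:

```
PSN: beta=13, scale-free fit R2=0.832
selected 397 features -> 12 centralities
best DNN: arch=[8, 8, 8, 2] opt=adam lr=0.001 d=0.3
validation bACC = 0.913
```

The PSN's weighted degree distribution fits a power law (R² = 0.83 ≥ 0.8),
the 2000-feature cohort collapses to 12 topological features, and the best
grid-searched network separates the 4:1-imbalanced classes at bACC 0.91 on
the held-out validation partition (0.5 would be chance).

For transfer, extract centralities from a second platform view of the same
cohort and apply the frozen model:

```python
a, b, outcomes = generate_platform_pair(cfg, "rank-monotone")
# ... train on view A's centralities as above, then:
bacc_external = external_validate(best.model, feats_b, y)
```

A command-line interface mirrors the stages: `psntopo simulate`, `select`,
`graph`, `topo`, and `run --config run.yaml` for the full orchestrated
pipeline (artifacts, records.csv and a seed manifest in an output
directory).

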