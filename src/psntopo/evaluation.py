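"""Model scoring and comparison: balanced accuracy, ANOVA/Tukey, transfer.

Balanced accuracy (bACC), the mean of sensitivity and specificity, is the
single performance measure — the cohorts are imbalanced (4:1 or 2:1), so raw
accuracy would reward majority voting. Groups of models are compared with a
one-way ANOVA followed by post-hoc Tukey HSD tests at a 0.01 significance
threshold; pairwise mean differences are reported with 95% confidence
intervals (delta-bACC).

The external-validation (transfer) harness applies a frozen model to
topological features extracted from another cohort: each cohort gets its own
PSN and centralities, columns are aligned by metric name, and
standardization reuses the training cohort's scaler. Module-membership
features are cohort-specific and refuse to transfer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Callable, Sequence

import numpy as np

from psntopo.topology import Scaler, TopoFeatureMatrix, standardize

if TYPE_CHECKING:  # avoid a circular import; classifiers imports EvalRecord
    from psntopo.classifiers import TrainedModel


@dataclass
class EvalRecord:
    """One trained model's configuration, seed and bACC on a named partition."""

    family: str
    config: str
    seed: int
    partition: str
    bacc: float
    eval_bacc: float = float("nan")
    dataset_tag: str = ""
    feature_set: str = ""
    complexity: tuple = ()
    model: object = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.bacc <= 1.0:
            raise ValueError("bACC must lie in [0, 1]")


@dataclass
class PairResult:
    groups: tuple[str, str]
    delta_bacc: float       # mean(group2) - mean(group1)
    ci_low: float
    ci_high: float
    pvalue: float
    significant: bool


@dataclass
class GroupComparison:
    group_labels: list[str]
    anova_pvalue: float
    pairs: list[PairResult]
    alpha: float = 0.01


def balanced_accuracy(y_true, y_pred) -> float:
    """Mean of the two per-class recalls, (sensitivity + specificity) / 2."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    classes = np.unique(y_true)
    if classes.size != 2:
        raise ValueError("y_true must contain both classes")
    recalls = [np.mean(y_pred[y_true == c] == c) for c in classes]
    return float(np.mean(recalls))


def compare_groups(
    records: Sequence[EvalRecord],
    grouping: str | Callable[[EvalRecord], str],
    alpha: float = 0.01,
) -> GroupComparison:
    """One-way ANOVA across record groups on bACC, plus Tukey HSD pairs.

    ``grouping`` is an EvalRecord attribute name (e.g. 'feature_set',
    'dataset_tag', 'family') or a callable. Each pair is reported with its
    delta-bACC (mean difference), 95% Tukey confidence interval and adjusted
    p-value; significance uses the stated threshold (default 0.01).
    """
    from scipy.stats import f_oneway
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    key = grouping if callable(grouping) else (lambda r: getattr(r, grouping))
    groups: dict[str, list[float]] = {}
    for r in records:
        groups.setdefault(str(key(r)), []).append(r.bacc)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group '{g}' has fewer than 2 records")
    arrays = [np.asarray(v) for v in groups.values()]
    if all(np.ptp(a) == 0 for a in arrays):
        raise ValueError("zero within-group variance in every group")
    anova_p = float(f_oneway(*arrays).pvalue)

    values = np.concatenate(arrays)
    labels = np.concatenate([[g] * len(v) for g, v in groups.items()])
    tk = pairwise_tukeyhsd(values, labels, alpha=0.05)  # 95% CIs
    import itertools

    pair_names = list(itertools.combinations([str(g) for g in tk.groupsunique], 2))
    pairs = []
    for row in range(len(tk.meandiffs)):
        g1, g2 = pair_names[row]
        pairs.append(PairResult(
            groups=(g1, g2),
            delta_bacc=float(tk.meandiffs[row]),
            ci_low=float(tk.confint[row][0]),
            ci_high=float(tk.confint[row][1]),
            pvalue=float(tk.pvalues[row]),
            significant=bool(tk.pvalues[row] < alpha),
        ))
    return GroupComparison(sorted(groups), anova_p, pairs, alpha)


def best_model(records: Sequence[EvalRecord],
               scope: str | Callable[[EvalRecord], str] | None = None):
    """The record with the best bACC, optionally one winner per scope value.

    Ties are broken by simpler configuration (the spec's complexity key:
    fewer/smaller layers for the DNN) and then by lower seed, so the result
    is deterministic.
    """
    recs = list(records)
    if not recs:
        raise ValueError("no records")

    def pick(rs: Sequence[EvalRecord]) -> EvalRecord:
        return min(rs, key=lambda r: (-r.bacc, r.complexity, r.seed))

    if scope is None:
        return pick(recs)
    key = scope if callable(scope) else (lambda r: getattr(r, scope))
    by_scope: dict[str, list[EvalRecord]] = {}
    for r in recs:
        by_scope.setdefault(str(key(r)), []).append(r)
    return {s: pick(rs) for s, rs in by_scope.items()}


def external_validate(
    model: "TrainedModel",
    external_features: TopoFeatureMatrix,
    external_y: np.ndarray,
    scaler: Scaler | None = None,
    restandardize: bool = True,
) -> float:
    """bACC of a frozen model on an independent cohort's topological features.

    The external cohort must come through the same pipeline (its own PSN,
    its own soft-threshold power, its own centralities). Columns are aligned
    to the model's features by metric name (the part after the dataset tag),
    so the model applies unchanged even when the external cohort's original
    feature count differs. Module-membership features are cohort-specific
    and raise.

    By default the external cohort's features are z-scored on that cohort
    (``restandardize=True``): centrality magnitudes depend on the cohort's
    own soft-threshold power, so each cohort's features must be normalized
    on that cohort for the topological feature spaces to be comparable.
    Passing ``restandardize=False`` with the training cohort's ``scaler``
    applies frozen preprocessing instead. Model parameters are hashed before
    and after scoring to assert nothing was refitted.
    """
    model_metrics = [n.split(":", 1)[-1] for n in model.feature_names]
    if any("module" in m for m in model_metrics):
        raise ValueError(
            "module-membership features do not transfer across cohorts "
            "(module identities are cohort-specific); train a "
            "centralities-only model for external validation"
        )
    ext_metrics = [n.split(":", 1)[-1] for n in external_features.feature_names]
    try:
        col_idx = [ext_metrics.index(m) for m in model_metrics]
    except ValueError as e:
        raise ValueError(
            f"external features lack a metric required by the model: {e}"
        ) from None
    values = external_features.values[:, col_idx]
    aligned = TopoFeatureMatrix(
        values, list(model.feature_names), list(external_features.sample_ids),
        external_features.feature_set,
    )
    if restandardize or scaler is None:
        feats_values = standardize(aligned).values
    else:  # frozen preprocessing with the training cohort's scaler
        # frozen preprocessing: the scaler's kept columns are exactly the
        # model's features, so apply its statistics directly
        scaler_metrics = [n.split(":", 1)[-1] for n in scaler.feature_names]
        if scaler_metrics != model_metrics:
            raise ValueError("scaler features do not match the model's features")
        feats_values = (values - scaler.mean) / scaler.std

    hash_before = model.param_hash()
    pred = model.predict(feats_values)
    bacc = balanced_accuracy(np.asarray(external_y), pred)
    assert model.param_hash() == hash_before, "frozen-model contract violated"
    return bacc
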