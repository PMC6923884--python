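"""Per-feature Wilcoxon rank-sum screening against a binary outcome.

Features are screened on training samples only (the test partition's labels
are never visible to this module). Each feature gets a two-sided Wilcoxon
rank-sum (Mann-Whitney) p-value; features with P < alpha are kept. If no
feature passes — which happens for weakly informative cohorts — the top 5%
smallest-P features are kept regardless of their p-values.

No multiple-testing correction is applied: the screen is a raw P < 0.05
filter by design, trading specificity for recall ahead of the network step.
The exact rank-sum null distribution is used for per-class sizes <= 12
without ties; otherwise the normal approximation with tie and continuity
corrections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

EXACT_MAX_N = 12  # per-class size up to which the exact null is enumerated


@dataclass
class SelectionResult:
    pvalues: np.ndarray
    selected: np.ndarray  # sorted feature indices
    alpha: float
    fallback_used: bool
    fallback_frac: float


def wilcoxon_pvalues(X_train: np.ndarray, y_train: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p-value per feature (ties -> midranks).

    Parameters
    ----------
    X_train : array (n_samples, n_features)
    y_train : binary array (n_samples,)
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"y_train must contain exactly two classes, got {classes}")
    g0, g1 = X[y == classes[0]], X[y == classes[1]]
    if len(g0) < 2 or len(g1) < 2:
        raise ValueError("need at least 2 samples per class")
    small = min(len(g0), len(g1)) <= EXACT_MAX_N
    p = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        a, b = g1[:, j], g0[:, j]
        if np.ptp(X[:, j]) == 0:  # identical in both groups: no evidence at all
            p[j] = 1.0
            continue
        has_ties = np.unique(np.concatenate([a, b])).size < len(a) + len(b)
        method = "exact" if (small and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                                 use_continuity=True)
        p[j] = min(float(res.pvalue), 1.0)
    return p


def select_features(
    pvalues: np.ndarray, alpha: float = 0.05, fallback_frac: float = 0.05
) -> SelectionResult:
    """Keep features with P < alpha; fall back to the smallest-P top fraction.

    The fallback keeps exactly ``ceil(fallback_frac * p)`` features; ties at
    the boundary are resolved by feature index order (stable sort).
    """
    p = np.asarray(pvalues, dtype=float)
    if not np.isfinite(p).all():
        raise ValueError("p-values must be finite")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    selected = np.flatnonzero(p < alpha)
    fallback_used = False
    if selected.size == 0:
        k = math.ceil(fallback_frac * p.size)
        order = np.argsort(p, kind="stable")  # ties broken by feature index
        selected = np.sort(order[:k])
        fallback_used = True
    return SelectionResult(p, selected, alpha, fallback_used, fallback_frac)
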