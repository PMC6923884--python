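"""Patient similarity network (PSN) inference.

Patient profiles are compared pairwise with Pearson correlation, the
correlations are rescaled to positive edge weights with the signed WGCNA
soft-threshold transform ``a_ij = ((1 + r_ij) / 2) ** beta``, and the power
``beta`` is chosen as the smallest integer for which the weighted degree
distribution is approximately scale-free (log-log fit R^2 above a target).
The resulting graph is fully connected: nodes are patients, weights lie in
(0, 1].

The network is transductive by design: it is built from every sample of a
cohort (training and test patients together) and never sees outcome labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Weight assigned to a perfectly anti-correlated pair so the graph stays
#: literally fully connected (the transform alone would give 0).
MIN_WEIGHT = 1e-12


@dataclass
class CorrelationMatrix:
    """Symmetric patient-patient Pearson correlation matrix with unit diagonal."""

    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("correlation matrix must be square")
        if v.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length does not match matrix")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-8):
            raise ValueError("correlation matrix must have unit diagonal")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class PatientGraph:
    """Fully connected weighted graph over patients.

    ``weights[i, j]`` is the edge weight a_ij in (0, 1]; the diagonal is zero
    by convention. ``beta`` is the soft-threshold power used to build it and
    ``fit_r2`` the scale-free (log-log degree) fit achieved.
    """

    weights: np.ndarray
    beta: float
    sample_ids: list[str]
    fit_r2: float = float("nan")

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weight matrix must be square")
        if w.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length does not match weights")
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("self-weights must be zero")
        off = w[~np.eye(w.shape[0], dtype=bool)]
        if off.size and (off.min() <= 0 or off.max() > 1 + 1e-12):
            raise ValueError("off-diagonal weights must lie in (0, 1]")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        self.weights = w

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    def weighted_degrees(self) -> np.ndarray:
        return self.weights.sum(axis=1)

    def to_networkx(self):
        """Export as a networkx Graph with 'weight' (similarity) and 'dist'
        (1 / weight) edge attributes, plus beta / fit_r2 graph attributes."""
        import networkx as nx

        g = nx.Graph(beta=float(self.beta), fit_r2=float(self.fit_r2))
        g.add_nodes_from(self.sample_ids)
        n = self.n
        for i in range(n):
            for j in range(i + 1, n):
                w = self.weights[i, j]
                g.add_edge(
                    self.sample_ids[i], self.sample_ids[j],
                    weight=float(w), dist=float(1.0 / w),
                )
        return g


def pearson_matrix(X: np.ndarray, sample_ids: Sequence[str]) -> CorrelationMatrix:
    """Pearson correlation between all patient profiles pairwise.

    Parameters
    ----------
    X : array (n_samples, n_features)
        One row per patient profile.
    sample_ids : sequence of str

    Raises
    ------
    ValueError
        If any profile is constant (zero variance), naming the sample.
    """
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=1)
    bad = np.where(sd == 0)[0]
    if bad.size:
        names = [sample_ids[i] for i in bad]
        raise ValueError(f"constant profile(s) with zero variance: {names}")
    r = np.corrcoef(X)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(r, list(sample_ids))


def adjacency(cor: CorrelationMatrix, beta: float) -> PatientGraph:
    """Signed WGCNA soft-threshold transform of a correlation matrix.

    s_ij = (1 + r_ij) / 2 and a_ij = s_ij ** beta for i != j; a_ii = 0.
    An exactly anti-correlated pair (r = -1) maps to ``MIN_WEIGHT`` instead of
    0 so the graph remains fully connected.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    s = (1.0 + cor.values) / 2.0
    a = s ** beta
    a = np.maximum(a, MIN_WEIGHT)
    np.fill_diagonal(a, 0.0)
    return PatientGraph(a, float(beta), list(cor.sample_ids))


@dataclass
class ScaleFreeFit:
    """Goodness of a power-law fit to a weighted degree distribution.

    ``r2`` is the R^2 of regressing log10(bin frequency) on log10(mean degree
    in bin) over equal-width degree bins (the WGCNA scaleFreeFitIndex
    convention); ``degenerate`` marks inputs where the fit is undefined
    (fewer than 3 non-empty bins, e.g. all degrees equal), in which case
    ``r2`` is NaN.
    """

    r2: float
    slope: float
    n_bins_used: int
    degenerate: bool


def scale_free_fit(graph_or_degrees, n_bins: int = 10) -> ScaleFreeFit:
    """Scale-free topology fit R^2 of a graph's weighted degree distribution."""
    if isinstance(graph_or_degrees, PatientGraph):
        k = graph_or_degrees.weighted_degrees()
    else:
        k = np.asarray(graph_or_degrees, dtype=float)
    if k.size < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} degrees, got {k.size}")
    if np.any(k <= 0):
        raise ValueError("weighted degrees must be positive")
    lo, hi = k.min(), k.max()
    if (hi - lo) < 1e-12 * max(hi, 1.0):  # all degrees (numerically) equal
        return ScaleFreeFit(float("nan"), float("nan"), 0, True)
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = idx == b
        cnt = int(mask.sum())
        if cnt == 0:
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(cnt / k.size))
    if len(xs) < 3:
        return ScaleFreeFit(float("nan"), float("nan"), len(xs), True)
    res = stats.linregress(xs, ys)
    return ScaleFreeFit(float(res.rvalue ** 2), float(res.slope), len(xs), False)


def soft_threshold_power(
    cor: CorrelationMatrix,
    candidate_powers: Iterable[int] = range(1, 21),
    r2_target: float = 0.8,
    n_bins: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Choose the soft-threshold power by the scale-free topology criterion.

    For each candidate power the adjacency, weighted degrees and log-log fit
    R^2 are computed; the smallest power reaching ``r2_target`` is returned,
    or, if none does, the power with the best R^2. Returns ``(beta, table)``
    where the table has one row per candidate (beta, r2, slope, mean_k,
    median_k, max_k, degenerate).
    """
    if cor.n < 10:
        raise ValueError("need at least 10 samples to assess scale-free fit")
    rows = []
    for beta in candidate_powers:
        g = adjacency(cor, beta)
        k = g.weighted_degrees()
        fit = scale_free_fit(k, n_bins=n_bins)
        rows.append(
            dict(beta=int(beta), r2=fit.r2, slope=fit.slope,
                 mean_k=float(k.mean()), median_k=float(np.median(k)),
                 max_k=float(k.max()), degenerate=fit.degenerate)
        )
    table = pd.DataFrame(rows)
    if table["degenerate"].all():
        # e.g. all pairwise correlations equal: every power gives equal degrees
        table.attrs["warning"] = "degenerate degree distribution; beta=1"
        return 1, table
    ok = table[~table["degenerate"] & (table["r2"] >= r2_target)]
    if len(ok):
        beta = int(ok["beta"].iloc[0])
    else:
        valid = table[~table["degenerate"]]
        beta = int(valid.loc[valid["r2"].idxmax(), "beta"])
    return beta, table


def build_psn(
    X: np.ndarray,
    sample_ids: Sequence[str],
    beta: int | str = "auto",
    r2_target: float = 0.8,
) -> PatientGraph:
    """Full PSN construction: Pearson -> soft threshold -> adjacency.

    ``beta='auto'`` selects the power by the scale-free criterion; an integer
    fixes it. The achieved fit R^2 is recorded on the graph.
    """
    cor = pearson_matrix(X, sample_ids)
    if beta == "auto":
        beta, _ = soft_threshold_power(cor, r2_target=r2_target)
    graph = adjacency(cor, int(beta))
    graph.fit_r2 = scale_free_fit(graph).r2
    return graph
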