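"""Per-patient topological features of a PSN: 12 centralities and modules.

Centralities treat edge weights a_ij in (0, 1] as similarities. Shortest-path
based metrics (closeness, load) run on the induced distances d = 1/a;
current-flow metrics use a as conductance; the eigenvector family
(eigenvector, Katz, HITS, PageRank) works on the weights directly. The two
iterative metrics are peeling variants: the base metric is recomputed on the
surviving subgraph, the current maximum node records its score and is
removed, until the graph is empty.

Module-membership features are binary one-hot indicators of graph modules
found either by normalized-Laplacian spectral clustering (module count chosen
by the largest eigengap) or by a weighted stochastic block model (Gaussian
block means, block count chosen by BIC). Because module identities are
cohort-specific, module features do not transfer across cohorts; the twelve
centralities do — their number and meaning are independent of the original
feature count, which is what makes cross-platform model transfer possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from psntopo.psn import PatientGraph

CENTRALITY_NAMES = [
    "weighted_degree",
    "closeness",
    "currentflow_closeness",
    "currentflow_betweenness",
    "eigenvector",
    "katz",
    "hits",
    "pagerank",
    "load",
    "clustering_coef",
    "iterative_weighted_degree",
    "iterative_clustering_coef",
]

_POWER_TOL = 1e-10
_POWER_MAXITER = 10_000
_PAGERANK_DAMPING = 0.85
_KATZ_ALPHA_FRAC = 0.9  # attenuation = 0.9 / lambda_max


@dataclass
class CentralityMatrix:
    """n x 12 matrix of per-patient centralities, columns in CENTRALITY_NAMES order."""

    values: np.ndarray
    metric_names: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.sample_ids), len(self.metric_names)):
            raise ValueError("centrality matrix shape mismatch")
        if not np.isfinite(v).all():
            raise ValueError("centrality matrix contains non-finite values")
        self.values = v


@dataclass
class ModuleAssignment:
    """Hard assignment of every patient to exactly one graph module."""

    labels: np.ndarray
    k: int
    method: str  # 'spectral' or 'sbm'
    objective_trace: dict[int, float] = field(default_factory=dict)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.min() < 0 or self.labels.max() >= self.k:
            raise ValueError("labels must lie in [0, k)")


@dataclass
class TopoFeatureMatrix:
    """Samples x topological-features matrix with provenance-tagged names."""

    values: np.ndarray
    feature_names: list[str]
    sample_ids: list[str]
    feature_set: str  # 'centralities' | 'modularities' | 'both'
    standardized: bool = False
    n_dropped: int = 0  # zero-variance columns removed by standardization

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.sample_ids), len(self.feature_names)):
            raise ValueError("feature matrix shape mismatch")
        self.values = v

    @property
    def d(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# centralities
# ---------------------------------------------------------------------------

def _strength(W: np.ndarray) -> np.ndarray:
    return W.sum(axis=1)


def _onnela_clustering(W: np.ndarray) -> np.ndarray:
    """Weighted local clustering coefficient (geometric-mean / Onnela form).

    Weights are normalized by the maximum weight in the (sub)graph; nodes with
    fewer than two neighbours get 0.
    """
    n = W.shape[0]
    if n == 0:
        return np.zeros(0)
    wmax = W.max()
    if wmax <= 0:
        return np.zeros(n)
    Wh = np.cbrt(W / wmax)
    tri = np.diag(Wh @ Wh @ Wh)  # 2 * sum over triangles of geometric means
    deg = (W > 0).sum(axis=1)
    out = np.zeros(n)
    ok = deg >= 2
    out[ok] = tri[ok] / (deg[ok] * (deg[ok] - 1))
    return out


def iterative_centrality(graph: PatientGraph | np.ndarray,
                         base: str = "weighted_degree") -> np.ndarray:
    """Peeling centrality: repeatedly remove the current top node.

    At each step the base metric ('weighted_degree' or 'clustering_coef') is
    computed on the surviving subgraph; the node with the maximum value (ties
    broken by lowest index) records that value as its feature and is removed.
    Every node therefore gets its score at removal time.
    """
    if base == "weighted_degree":
        metric = _strength
    elif base == "clustering_coef":
        metric = _onnela_clustering
    else:
        raise ValueError(f"unknown base metric '{base}'")
    W = graph.weights if isinstance(graph, PatientGraph) else np.asarray(graph, float)
    n = W.shape[0]
    out = np.empty(n)
    alive = list(range(n))
    sub = W.copy()
    while alive:
        scores = metric(sub)
        # lowest index among maxima, with a tolerance so that exact ties
        # (e.g. the three nodes of a triangle) break identically regardless
        # of floating-point evaluation order
        mx = scores.max()
        top = int(np.flatnonzero(scores >= mx - 1e-9 * (1.0 + abs(mx)))[0])
        out[alive[top]] = scores[top]
        del alive[top]
        sub = np.delete(np.delete(sub, top, axis=0), top, axis=1)
    return out


def _shortest_path_closeness(W: np.ndarray) -> np.ndarray:
    """Closeness (n-1) / sum_j d(i, j) on the induced distances d = 1/a."""
    from scipy.sparse.csgraph import shortest_path

    n = W.shape[0]
    D = np.zeros_like(W)
    nz = W > 0
    D[nz] = 1.0 / W[nz]
    dist = shortest_path(D, method="D", directed=False)
    return (n - 1) / dist.sum(axis=1)


def _laplacian_pinv(W: np.ndarray) -> np.ndarray:
    L = np.diag(W.sum(axis=1)) - W
    return np.linalg.pinv(L)


def _currentflow_closeness(W: np.ndarray) -> np.ndarray:
    """1 / total effective resistance to all other nodes (weights are
    conductances)."""
    Lp = _laplacian_pinv(W)
    d = np.diag(Lp)
    R = d[:, None] + d[None, :] - 2 * Lp  # pairwise effective resistances
    return 1.0 / R.sum(axis=1)


def _currentflow_betweenness(W: np.ndarray) -> np.ndarray:
    """Current-flow (random-walk) betweenness, normalized by (n-1)(n-2)/2.

    For a unit current injected at s and removed at t, the current on edge
    (i, j) is a_ij |p_i - p_j| with potentials p = Lp[:, s] - Lp[:, t]; a
    node's throughput for the pair is half the absolute current through it
    (endpoints count 1). Summing |F_s - F_t| over all pairs s < t for each
    edge reduces to a sort: sum_{s<t} |x_s - x_t| = sum_k (2k - n + 1) x_(k).
    """
    n = W.shape[0]
    Lp = _laplacian_pinv(W)
    coef = 2.0 * np.arange(n) - n + 1.0
    through = np.zeros(n)
    for i in range(n):
        jj = np.flatnonzero(W[i])
        F = Lp[i][None, :] - Lp[jj]          # F[j, s] = Lp[i,s] - Lp[j,s]
        F.sort(axis=1)
        B = F @ coef                         # sum over pairs of |F_s - F_t|
        through[i] = 0.5 * (W[i, jj] @ B)
    # each node is an endpoint of (n-1) pairs; half-sum counts those as 1/2
    bet = through + 0.5 * (n - 1)
    return (bet - (n - 1)) / ((n - 1) * (n - 2) / 2.0)


def compute_centralities(graph: PatientGraph) -> CentralityMatrix:
    """All twelve centrality metrics for every patient of a PSN.

    Iterative solvers (eigenvector, Katz, HITS, PageRank) use power iteration
    with tolerance 1e-10 and at most 10,000 iterations; non-convergence is a
    hard error naming the metric. HITS hub and authority scores coincide on an
    undirected graph; the hub score is reported.
    """
    W = graph.weights
    n = graph.n
    ids = graph.sample_ids
    G = graph.to_networkx()
    cols: dict[str, np.ndarray] = {}

    cols["weighted_degree"] = _strength(W)
    cols["closeness"] = _shortest_path_closeness(W)
    cols["currentflow_closeness"] = _currentflow_closeness(W)
    cols["currentflow_betweenness"] = _currentflow_betweenness(W)
    try:
        cols["eigenvector"] = _as_vec(
            nx.eigenvector_centrality(G, weight="weight", tol=_POWER_TOL,
                                      max_iter=_POWER_MAXITER), ids)
    except nx.PowerIterationFailedConvergence as e:
        raise RuntimeError("eigenvector centrality failed to converge") from e
    lam = float(np.linalg.eigvalsh(W)[-1])
    try:
        cols["katz"] = _as_vec(
            nx.katz_centrality(G, alpha=_KATZ_ALPHA_FRAC / lam, weight="weight",
                               tol=n * _POWER_TOL, max_iter=_POWER_MAXITER), ids)
    except nx.PowerIterationFailedConvergence as e:
        raise RuntimeError("katz centrality failed to converge") from e
    try:
        hubs, _ = nx.hits(G, max_iter=_POWER_MAXITER, tol=_POWER_TOL)
    except nx.PowerIterationFailedConvergence as e:
        raise RuntimeError("hits centrality failed to converge") from e
    cols["hits"] = _as_vec(hubs, ids)
    try:
        cols["pagerank"] = _as_vec(
            nx.pagerank(G, alpha=_PAGERANK_DAMPING, weight="weight",
                        tol=_POWER_TOL, max_iter=_POWER_MAXITER), ids)
    except nx.PowerIterationFailedConvergence as e:
        raise RuntimeError("pagerank centrality failed to converge") from e
    cols["load"] = _as_vec(nx.load_centrality(G, weight="dist", normalized=True), ids)
    cols["clustering_coef"] = _onnela_clustering(W)
    cols["iterative_weighted_degree"] = iterative_centrality(graph, "weighted_degree")
    cols["iterative_clustering_coef"] = iterative_centrality(graph, "clustering_coef")

    values = np.column_stack([cols[name] for name in CENTRALITY_NAMES])
    return CentralityMatrix(values, list(CENTRALITY_NAMES), list(ids))


def _as_vec(d: dict, ids: Sequence[str]) -> np.ndarray:
    return np.array([d[s] for s in ids], dtype=float)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

def _spectral_embedding(W: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues and the first-k-eigenvector embedding of the normalized
    Laplacian, rows scaled to unit norm (Ng-Jordan-Weiss)."""
    d = W.sum(axis=1)
    if np.any(d <= 0):
        raise ValueError("graph has an isolated node")
    dinv = 1.0 / np.sqrt(d)
    L = np.eye(W.shape[0]) - dinv[:, None] * W * dinv[None, :]
    vals, vecs = np.linalg.eigh(L)
    U = vecs[:, :k]
    norms = np.linalg.norm(U, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return vals, U / norms


def spectral_modules(graph: PatientGraph, k_max: int = 15,
                     seed: int = 0) -> ModuleAssignment:
    """Normalized-Laplacian spectral clustering with eigengap model selection.

    The module count k in [2, k_max] maximizes the eigengap
    lambda_{k+1} - lambda_k of the normalized Laplacian spectrum (ties go to
    the smaller k); the embedding is clustered with seeded k-means.
    """
    from sklearn.cluster import KMeans

    n = graph.n
    if n <= k_max:
        raise ValueError(f"need n > k_max, got n={n}, k_max={k_max}")
    vals, _ = _spectral_embedding(graph.weights, k_max + 1)
    n_zero = int(np.sum(vals < 1e-10))
    if n_zero > k_max:
        raise ValueError(f"{n_zero} connected components exceed k_max={k_max}")
    gaps = {k: float(vals[k] - vals[k - 1]) for k in range(2, k_max + 1)}
    k = max(gaps, key=lambda kk: (gaps[kk], -kk))
    _, U = _spectral_embedding(graph.weights, k)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(U)
    labels = _canonical_labels(km.labels_)
    return ModuleAssignment(labels, k, "spectral", gaps, list(graph.sample_ids))


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel modules by order of first appearance (node-order equivariance)."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


class _BlockStats:
    """Sufficient statistics (count, sum, sum of squares) of edge weights per
    unordered block pair, with O(B^2) single-node move updates."""

    def __init__(self, W: np.ndarray, labels: np.ndarray, B: int):
        self.W = W
        self.B = B
        self.labels = labels.copy()
        self.N = np.zeros((B, B))
        self.S1 = np.zeros((B, B))
        self.S2 = np.zeros((B, B))
        iu = np.triu_indices_from(W, k=1)
        for a, b, w in zip(labels[iu[0]], labels[iu[1]], W[iu]):
            lo, hi = (a, b) if a <= b else (b, a)
            self.N[lo, hi] += 1
            self.S1[lo, hi] += w
            self.S2[lo, hi] += w * w

    def _node_stats(self, i: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-block (count, sum, sumsq) of node i's incident edge weights."""
        w = self.W[i].copy()
        w[i] = 0.0
        lab = self.labels
        ng = np.bincount(lab, minlength=self.B).astype(float)
        ng[lab[i]] -= 1  # exclude i itself
        s1 = np.bincount(lab, weights=w, minlength=self.B)
        s2 = np.bincount(lab, weights=w * w, minlength=self.B)
        return ng, s1, s2

    def _apply(self, i: int, old: int, new: int, sign: float,
               ng, s1, s2) -> None:
        for g in range(self.B):
            if ng[g] == 0 and s1[g] == 0:
                continue
            lo, hi = (old, g) if old <= g else (g, old)
            self.N[lo, hi] -= sign * ng[g]
            self.S1[lo, hi] -= sign * s1[g]
            self.S2[lo, hi] -= sign * s2[g]
            lo, hi = (new, g) if new <= g else (g, new)
            self.N[lo, hi] += sign * ng[g]
            self.S1[lo, hi] += sign * s1[g]
            self.S2[lo, hi] += sign * s2[g]

    def move(self, i: int, new: int) -> None:
        old = self.labels[i]
        if new == old:
            return
        ng, s1, s2 = self._node_stats(i)
        self._apply(i, old, new, 1.0, ng, s1, s2)
        self.labels[i] = new

    def sse(self) -> float:
        mask = self.N > 0
        return float((self.S2[mask] - self.S1[mask] ** 2 / self.N[mask]).sum())

    def n_pairs_used(self) -> int:
        return int((self.N > 0).sum())


def _sbm_objective(stats: _BlockStats, n: int, m: int) -> float:
    """BIC-style description length of a Gaussian weighted block model.

    -2 max-loglik + (number of block-pair means + 1) * log(m) plus a label-
    coding term 2 * n * H(block proportions), which penalizes the partition
    itself (an ICL-like correction; plain BIC overfits the block count
    because greedy label search can always shave residual variance).
    """
    sigma2 = max(stats.sse() / m, 1e-12)
    neg2ll = m * (np.log(2 * np.pi * sigma2) + 1.0)
    prop = np.bincount(stats.labels, minlength=stats.B) / n
    prop = prop[prop > 0]
    entropy = float(-(prop * np.log(prop)).sum())
    return neg2ll + (stats.n_pairs_used() + 1) * np.log(m) + 2 * n * entropy


def _fit_gaussian_sbm(W: np.ndarray, B: int, seed: int,
                      max_sweeps: int = 30) -> tuple[np.ndarray, float]:
    """Fit a B-block Gaussian weighted block model: spectral-k-means init
    followed by greedy single-node reassignment sweeps on the description-
    length objective."""
    from sklearn.cluster import KMeans

    n = W.shape[0]
    m = n * (n - 1) // 2
    if B == 1:
        stats = _BlockStats(W, np.zeros(n, dtype=int), 1)
        return stats.labels, _sbm_objective(stats, n, m)
    _, U = _spectral_embedding(W, min(B, n - 1))
    km = KMeans(n_clusters=B, n_init=5, random_state=seed).fit(U)
    stats = _BlockStats(W, km.labels_.astype(int), B)
    best = _sbm_objective(stats, n, m)
    for _ in range(max_sweeps):
        improved = False
        for i in range(n):
            current = int(stats.labels[i])
            block_sizes = np.bincount(stats.labels, minlength=B)
            if block_sizes[current] <= 1:
                continue  # keep all B blocks populated
            best_b, best_obj = current, best
            for b in range(B):
                if b == current:
                    continue
                stats.move(i, b)
                cand = _sbm_objective(stats, n, m)
                if cand < best_obj - 1e-9:
                    best_b, best_obj = b, cand
                stats.move(i, current)
            if best_b != current:
                stats.move(i, best_b)
                best = best_obj
                improved = True
        if not improved:
            break
    return stats.labels.copy(), best


def sbm_modules(graph: PatientGraph, B_max: int = 50, seed: int = 0,
                n_restarts: int = 3) -> ModuleAssignment:
    """Weighted stochastic block model modules with automatic block count.

    Edge weights are modelled with Gaussian block-pair means and a pooled
    variance; the block count B minimizes BIC over candidates 1..B_max
    (the search stops early once BIC has worsened for three consecutive B).
    The fit is stochastic (seeded restarts of the k-means initialisation);
    ``objective_trace`` records the BIC of every candidate B evaluated.
    """
    if B_max < 2:
        raise ValueError("B_max must be >= 2")
    n = graph.n
    if n < 10:
        raise ValueError("need at least 10 samples for SBM fitting")
    W = graph.weights
    rng = np.random.default_rng(seed)
    trace: dict[int, float] = {}
    best_labels, best_bic, best_B = None, np.inf, 1
    worse_streak = 0
    for B in range(1, min(B_max, n - 1) + 1):
        bics = []
        labs = []
        for _ in range(n_restarts if B > 1 else 1):
            sub = int(rng.integers(0, 2**31 - 1))
            lab, b = _fit_gaussian_sbm(W, B, sub)
            bics.append(b)
            labs.append(lab)
        j = int(np.argmin(bics))
        trace[B] = float(bics[j])
        if bics[j] < best_bic:
            best_bic, best_labels, best_B = bics[j], labs[j], B
            worse_streak = 0
        else:
            worse_streak += 1
            if worse_streak >= 3:
                break
    labels = _canonical_labels(best_labels)
    return ModuleAssignment(labels, best_B, "sbm", trace, list(graph.sample_ids))


def module_indicator_features(assignment: ModuleAssignment) -> np.ndarray:
    """Exact one-hot encoding of a module assignment (n x k, row sums 1)."""
    n = assignment.labels.size
    out = np.zeros((n, assignment.k))
    out[np.arange(n), assignment.labels] = 1.0
    return out


# ---------------------------------------------------------------------------
# assembly / standardization
# ---------------------------------------------------------------------------

def assemble_features(
    parts: Sequence[tuple[CentralityMatrix | ModuleAssignment, str]],
    set_choice: str = "both",
) -> TopoFeatureMatrix:
    """Horizontally concatenate topological feature blocks.

    ``parts`` are (CentralityMatrix | ModuleAssignment, dataset_tag) pairs
    from one or several datasets over the same samples; ``set_choice``
    restricts to 'centralities', 'modularities' or keeps 'both'. Feature
    names carry provenance as '<tag>:<name>'. All parts must share sample ids
    and order.
    """
    if set_choice not in ("centralities", "modularities", "both"):
        raise ValueError(f"unknown feature set '{set_choice}'")
    blocks: list[np.ndarray] = []
    names: list[str] = []
    ref_ids: list[str] | None = None
    for obj, tag in parts:
        if isinstance(obj, CentralityMatrix):
            if set_choice == "modularities":
                continue
            vals, part_names, ids = obj.values, obj.metric_names, obj.sample_ids
        elif isinstance(obj, ModuleAssignment):
            if set_choice == "centralities":
                continue
            vals = module_indicator_features(obj)
            part_names = [f"{obj.method}_module{j}" for j in range(obj.k)]
            ids = obj.sample_ids
        else:
            raise TypeError(f"unsupported part type {type(obj)}")
        if ref_ids is None:
            ref_ids = list(ids)
        elif list(ids) != ref_ids:
            raise ValueError(f"sample-id mismatch in part tagged '{tag}'")
        blocks.append(np.asarray(vals, dtype=float))
        names.extend(f"{tag}:{nm}" for nm in part_names)
    if not blocks:
        raise ValueError(f"no parts match set_choice='{set_choice}'")
    return TopoFeatureMatrix(np.hstack(blocks), names, ref_ids, set_choice)


@dataclass
class Scaler:
    """Frozen per-feature z-scoring parameters (fitted on one sample subset)."""

    mean: np.ndarray
    std: np.ndarray
    keep: np.ndarray  # boolean mask of non-constant columns
    feature_names: list[str]

    def transform(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, dtype=float)[:, self.keep]
        return (v - self.mean) / self.std


def fit_scaler(features: TopoFeatureMatrix,
               fit_ids: Sequence[str]) -> Scaler:
    """Estimate per-feature mean/sd on ``fit_ids`` rows only (no leakage);
    zero-variance columns on the fit subset are dropped."""
    fit_ids = list(fit_ids)
    if not fit_ids:
        raise ValueError("empty fit set")
    pos = {s: i for i, s in enumerate(features.sample_ids)}
    idx = [pos[s] for s in fit_ids]
    sub = features.values[idx]
    mean = sub.mean(axis=0)
    std = sub.std(axis=0)
    keep = std > 1e-12
    return Scaler(mean[keep], std[keep], keep,
                  [n for n, k in zip(features.feature_names, keep) if k])


def standardize(features: TopoFeatureMatrix,
                fit_ids: Sequence[str] | None = None,
                scaler: Scaler | None = None) -> TopoFeatureMatrix:
    """Z-score features with mean/variance from ``fit_ids`` (default: all rows).

    The fitted statistics are applied to every row, so a scaler fitted on the
    training partition leaves test rows with non-zero means by design.
    Passing a pre-fitted ``scaler`` applies frozen preprocessing (the transfer
    harness uses this with the training cohort's scaler).
    """
    if scaler is None:
        scaler = fit_scaler(features, fit_ids if fit_ids is not None
                            else features.sample_ids)
    vals = scaler.transform(features.values)
    n_dropped = features.d - int(scaler.keep.sum())
    return TopoFeatureMatrix(vals, list(scaler.feature_names),
                             list(features.sample_ids), features.feature_set,
                             standardized=True, n_dropped=n_dropped)
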