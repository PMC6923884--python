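"""Definition-level brute-force oracles for the twelve centralities.

Every function here computes a metric straight from its textbook definition
with dense linear algebra, explicit path enumeration or scalar loops — no
shared code with the package implementation (which goes through networkx
power iteration, scipy shortest paths, Laplacian pseudo-inverse tricks and
vectorized peeling). Intended for graphs with n <= ~8 nodes.
"""

from __future__ import annotations

import itertools

import numpy as np


def floyd_warshall(W: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path distances on d = 1/w."""
    n = W.shape[0]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and W[i, j] > 0:
                D[i, j] = 1.0 / W[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


def weighted_degree(W: np.ndarray) -> np.ndarray:
    n = W.shape[0]
    return np.array([sum(W[i, j] for j in range(n) if j != i) for i in range(n)])


def closeness(W: np.ndarray) -> np.ndarray:
    n = W.shape[0]
    D = floyd_warshall(W)
    return np.array([(n - 1) / sum(D[i, j] for j in range(n) if j != i)
                     for i in range(n)])


def _effective_resistance(W: np.ndarray, i: int, j: int) -> float:
    """Solve the current-flow problem L v = e_i - e_j directly (grounded)."""
    n = W.shape[0]
    L = np.diag(W.sum(axis=1)) - W
    b = np.zeros(n)
    b[i], b[j] = 1.0, -1.0
    # ground node n-1 to make the system full rank
    v = np.zeros(n)
    v[:-1] = np.linalg.solve(L[:-1, :-1], b[:-1])
    return float(v[i] - v[j])


def currentflow_closeness(W: np.ndarray) -> np.ndarray:
    n = W.shape[0]
    out = np.empty(n)
    for i in range(n):
        out[i] = 1.0 / sum(_effective_resistance(W, i, j)
                           for j in range(n) if j != i)
    return out


def currentflow_betweenness(W: np.ndarray) -> np.ndarray:
    """Throughput of unit s-t currents, averaged over pairs.

    For each pair, potentials come from a grounded linear solve; a node's
    throughput is half the sum of absolute currents on its incident edges
    (endpoints count as 1). Normalization: (tau - (n-1)) / ((n-1)(n-2)/2).
    """
    n = W.shape[0]
    L = np.diag(W.sum(axis=1)) - W
    tau = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        b = np.zeros(n)
        b[s], b[t] = 1.0, -1.0
        v = np.zeros(n)
        v[:-1] = np.linalg.solve(L[:-1, :-1], b[:-1])
        for i in range(n):
            if i in (s, t):
                tau[i] += 1.0
            else:
                flow = sum(W[i, j] * abs(v[i] - v[j])
                           for j in range(n) if j != i)
                tau[i] += 0.5 * flow
    return (tau - (n - 1)) / ((n - 1) * (n - 2) / 2.0)


def eigenvector(W: np.ndarray) -> np.ndarray:
    """Leading eigenvector of W, positive, unit Euclidean norm."""
    vals, vecs = np.linalg.eigh(W)
    v = vecs[:, -1]
    if v.sum() < 0:
        v = -v
    return v / np.linalg.norm(v)


def katz(W: np.ndarray, alpha_frac: float = 0.9) -> np.ndarray:
    """Direct solve of (I - alpha W) x = beta 1 with alpha = 0.9/lambda_max,
    beta = 1, normalized to unit Euclidean norm."""
    lam = float(np.linalg.eigvalsh(W)[-1])
    alpha = alpha_frac / lam
    x = np.linalg.solve(np.eye(W.shape[0]) - alpha * W, np.ones(W.shape[0]))
    return x / np.linalg.norm(x)


def hits_hub(W: np.ndarray) -> np.ndarray:
    """Hub score: leading eigenvector of W W^T (= W^2 for symmetric W),
    normalized to sum 1 — coincides with the authority score here."""
    vals, vecs = np.linalg.eigh(W @ W.T)
    v = np.abs(vecs[:, -1])
    return v / v.sum()


def pagerank(W: np.ndarray, damping: float = 0.85) -> np.ndarray:
    """Stationary distribution of the damped weighted random walk, by a
    dense linear solve."""
    n = W.shape[0]
    P = W / W.sum(axis=1, keepdims=True)
    pr = np.linalg.solve(np.eye(n) - damping * P.T,
                         np.full(n, (1 - damping) / n))
    return pr / pr.sum()


def load(W: np.ndarray) -> np.ndarray:
    """Load centrality assuming unique shortest paths (true a.s. for random
    continuous weights): for each ordered pair (s, t), every interior node of
    the shortest s-t path gets 1; normalized by (n-1)(n-2)."""
    n = W.shape[0]
    D = np.full((n, n), np.inf)
    nxt = [[None] * n for _ in range(n)]
    for i in range(n):
        D[i, i] = 0.0
        for j in range(n):
            if i != j and W[i, j] > 0:
                D[i, j] = 1.0 / W[i, j]
                nxt[i][j] = j
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
                    nxt[i][j] = nxt[i][k]
    counts = np.zeros(n)
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            node = nxt[s][t]
            while node != t:
                counts[node] += 1.0
                node = nxt[node][t]
    return counts / ((n - 1) * (n - 2))


def clustering_onnela(W: np.ndarray) -> np.ndarray:
    n = W.shape[0]
    wmax = W.max()
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if j != i and W[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        s = 0.0
        for a in range(k):
            for b in range(a + 1, k):
                j, l = nbrs[a], nbrs[b]
                if W[j, l] > 0:
                    s += (W[i, j] / wmax * W[i, l] / wmax
                          * W[j, l] / wmax) ** (1.0 / 3.0)
        out[i] = 2.0 * s / (k * (k - 1))
    return out


def iterative_peel(W: np.ndarray, base) -> np.ndarray:
    """Peeling with score-at-removal, scalar re-indexing implementation."""
    n = W.shape[0]
    out = np.empty(n)
    alive = list(range(n))
    while alive:
        sub = W[np.ix_(alive, alive)]
        scores = base(sub)
        mx = scores.max()  # lowest index within numerical tolerance of the max
        top = int(np.flatnonzero(scores >= mx - 1e-9 * (1.0 + abs(mx)))[0])
        out[alive[top]] = scores[top]
        alive.pop(top)
    return out


ORACLES = {
    "weighted_degree": weighted_degree,
    "closeness": closeness,
    "currentflow_closeness": currentflow_closeness,
    "currentflow_betweenness": currentflow_betweenness,
    "eigenvector": eigenvector,
    "katz": katz,
    "hits": hits_hub,
    "pagerank": pagerank,
    "load": load,
    "clustering_coef": clustering_onnela,
    "iterative_weighted_degree":
        lambda W: iterative_peel(W, weighted_degree),
    "iterative_clustering_coef":
        lambda W: iterative_peel(W, clustering_onnela),
}


def random_complete_graph(rng: np.random.Generator, n: int,
                          low: float = 0.05, high: float = 1.0) -> np.ndarray:
    W = rng.uniform(low, high, (n, n))
    W = (W + W.T) / 2.0
    np.fill_diagonal(W, 0.0)
    return W


def max_oracle_error(compute_centralities, patient_graph_cls,
                     n_graphs: int = 100, seed: int = 0) -> float:
    """Worst |implementation - oracle| over random weighted graphs n <= 6."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_graphs):
        n = int(rng.integers(4, 7))
        W = random_complete_graph(rng, n)
        g = patient_graph_cls(W, 2.0, [f"s{i}" for i in range(n)])
        cm = compute_centralities(g)
        for col, name in enumerate(cm.metric_names):
            ref = ORACLES[name](W)
            err = float(np.abs(cm.values[:, col] - ref).max())
            worst = max(worst, err)
    return worst
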