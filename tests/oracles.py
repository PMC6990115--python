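"""Independent brute-force oracles used to validate the graph metrics and
the Tucker solver.  These deliberately avoid networkx and the package's
own linear-algebra path: distances come from Floyd-Warshall, shortest-path
counts from explicit dynamic programming, and the tiny Tucker problems are
solved by dense search over the unit sphere."""

from itertools import combinations

import numpy as np


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    dist = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(dist, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    return dist


def degree_oracle(adj: np.ndarray) -> np.ndarray:
    return np.asarray(adj).sum(axis=1).astype(float)


def betweenness_oracle(adj: np.ndarray) -> np.ndarray:
    """Normalized betweenness by explicit shortest-path counting.

    sigma[s, t] = number of shortest s-t paths (DP over the distance
    matrix); for each interior node v, paths through v are
    sigma[s, v] * sigma[v, t] when d(s,v) + d(v,t) = d(s,t).
    """
    n = adj.shape[0]
    dist = floyd_warshall(adj)
    sigma = np.zeros((n, n))
    for s in range(n):
        sigma[s, s] = 1.0
        finite = [v for v in range(n) if np.isfinite(dist[s, v])]
        for v in sorted(finite, key=lambda v: dist[s, v]):
            if v == s:
                continue
            sigma[s, v] = sum(
                sigma[s, u] for u in range(n) if adj[u, v] and dist[s, u] + 1 == dist[s, v]
            )
    bc = np.zeros(n)
    for v in range(n):
        for s, t in combinations([x for x in range(n) if x != v], 2):
            if not np.isfinite(dist[s, t]) or sigma[s, t] == 0:
                continue
            if dist[s, v] + dist[v, t] == dist[s, t]:
                bc[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    norm = (n - 1) * (n - 2) / 2
    return bc / norm if norm > 0 else bc


def clustering_oracle(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for v in range(n):
        nbrs = np.flatnonzero(adj[v])
        d = len(nbrs)
        if d < 2:
            continue
        links = sum(adj[a, b] for a, b in combinations(nbrs, 2))
        out[v] = 2.0 * links / (d * (d - 1))
    return out


def global_efficiency_oracle(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n < 2:
        return 0.0
    dist = floyd_warshall(adj)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(dist[i, j]) and dist[i, j] > 0:
                total += 1.0 / dist[i, j]
    return total / (n * (n - 1))


def local_efficiency_oracle(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n == 0:
        return 0.0
    total = 0.0
    for v in range(n):
        nbrs = np.flatnonzero(adj[v])
        if len(nbrs) < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        total += global_efficiency_oracle(sub)
    return total / n


def modularity_oracle(adj: np.ndarray, labels, gamma: float = 1.0) -> float:
    m = adj.sum() / 2.0
    if m == 0:
        return 0.0
    deg = adj.sum(axis=1)
    q = 0.0
    n = adj.shape[0]
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += adj[i, j] - gamma * deg[i] * deg[j] / (2.0 * m)
    return q / (2.0 * m)


def best_partition_oracle(adj: np.ndarray, gamma: float = 1.0):
    """Exhaustive modularity maximization over all set partitions (n <= 8)."""
    n = adj.shape[0]

    def partitions(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for p in partitions(rest):
            for i in range(len(p)):
                yield p[:i] + [p[i] + [first]] + p[i + 1 :]
            yield p + [[first]]

    best_q, best_p = -np.inf, None
    for p in partitions(list(range(n))):
        labels = np.empty(n, dtype=int)
        for lab, block in enumerate(p):
            for v in block:
                labels[v] = lab
        q = modularity_oracle(adj, labels, gamma)
        if q > best_q:
            best_q, best_p = q, p
    return best_q, best_p


def tucker_rank1_loss_oracle(W: np.ndarray, x_sq: float, n_theta: int = 20001) -> float:
    """Brute-force minimum loss for Q=1, R=1, K=2 instances.

    For a unit metric vector c(theta) = (cos t, sin t) the optimal region
    vector b is the top eigenvector of A(t) = sum_g (M_g c)(M_g c)^T, so
    the loss is x_sq - max_t lambda_max(A(t)), evaluated on a dense theta
    grid.  Uses only batched symmetric eigensolves, independent of the
    HOOI path.
    """
    G, J, K = W.shape
    assert K == 2
    theta = np.linspace(0.0, np.pi, n_theta)
    c = np.stack([np.cos(theta), np.sin(theta)], axis=1)  # N x 2
    v = np.einsum("gjk,nk->ngj", W, c)  # N x G x J
    A = np.einsum("ngi,ngj->nij", v, v)  # N x J x J
    lam = np.linalg.eigvalsh(A)[:, -1]
    return x_sq - float(lam.max())
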