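"""Independent brute-force oracles used only by the test suite.

Each function re-derives a quantity from first principles, staying
deliberately naive and separate from the package implementation.
"""

from collections import deque

import numpy as np


def constraint_enumeration(adj_und: np.ndarray, i: int) -> float:
    """Term-by-term evaluation of Burt's constraint on an undirected graph.

    Constraint_i = sum over direct contacts j of (P_ij + sum_q P_iq P_qj)^2
    with P_ij = 1/deg(i) for each contact j and q running over mutual
    contacts of i and j (q != i, j).
    """
    n = adj_und.shape[0]
    nbrs_i = [j for j in range(n) if adj_und[i, j]]
    if not nbrs_i:
        return float("nan")
    deg = adj_und.sum(axis=1)
    total = 0.0
    for j in nbrs_i:
        p_ij = 1.0 / len(nbrs_i)
        indirect = 0.0
        for q in nbrs_i:
            if q == j or q == i:
                continue
            if adj_und[q, j]:
                indirect += (1.0 / len(nbrs_i)) * (1.0 / deg[q])
        total += (p_ij + indirect) ** 2
    return total


def _bfs_counts(adj_und: np.ndarray, s: int):
    """Distances and shortest-path counts from s (unweighted BFS)."""
    n = adj_und.shape[0]
    dist = [-1] * n
    count = [0] * n
    dist[s], count[s] = 0, 1
    q = deque([s])
    while q:
        u = q.popleft()
        for v in range(n):
            if adj_und[u, v]:
                if dist[v] == -1:
                    dist[v] = dist[u] + 1
                    q.append(v)
                if dist[v] == dist[u] + 1:
                    count[v] += count[u]
    return dist, count


def betweenness_enumeration(adj_und: np.ndarray) -> np.ndarray:
    """Exhaustive shortest-path betweenness with multiplicity splitting.

    For every unordered pair (s, t) and every intermediate v, add
    sigma_st(v) / sigma_st where sigma_st(v) = sigma_sv * sigma_vt when
    d(s, v) + d(v, t) = d(s, t).
    """
    n = adj_und.shape[0]
    dists, counts = zip(*[_bfs_counts(adj_und, s) for s in range(n)])
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if dists[s][t] <= 0:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                if dists[s][v] >= 0 and dists[v][t] >= 0 and \
                        dists[s][v] + dists[v][t] == dists[s][t]:
                    bc[v] += counts[s][v] * counts[v][t] / counts[s][t]
    return bc


def leading_eigvec_dense(at: np.ndarray):
    """Leading eigenpair of a dense matrix via full eigendecomposition."""
    import scipy.linalg

    vals, vecs = scipy.linalg.eig(at)
    k = int(np.argmax(vals.real))
    lam = float(vals[k].real)
    v = np.abs(vecs[:, k].real)
    if v.max() > 0:
        v = v / v.max()
    return lam, v


def bh_stepup_naive(p):
    """Literal step-up definition: adj_i = min over j>=rank(i) of p_(j)m/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    sorted_p = p[order]
    for rank in range(m):
        candidates = [sorted_p[j] * m / (j + 1) for j in range(rank, m)]
        adj[order[rank]] = min(1.0, min(candidates))
    return adj
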