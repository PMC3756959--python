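"""Independent brute-force oracles used only by the tests.

Everything here is deliberately naive — exhaustive triangle counting,
exhaustive simple-path enumeration, per-pair residual regressions, full
enumeration of rank assignments — so it shares no code path with the
package implementations it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def bf_degree(adj: np.ndarray) -> np.ndarray:
    return np.array([sum(adj[i, j] for j in range(adj.shape[0]) if j != i)
                     for i in range(adj.shape[0])])


def bf_clustering_binary(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    C = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(1 for a, b in combinations(nbrs, 2) if adj[a, b] > 0)
        C[i] = 2.0 * links / (k * (k - 1))
    return C


def bf_clustering_weighted(adj: np.ndarray) -> np.ndarray:
    """Geometric-mean triangle clustering with max-normalized weights."""
    n = adj.shape[0]
    top = adj.max()
    W = adj / top if top > 0 else adj
    C = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        s = sum(
            (W[i, j] * W[i, h] * W[j, h]) ** (1.0 / 3.0)
            for j in nbrs
            for h in nbrs
            if h != j and adj[j, h] > 0
        )
        C[i] = s / (k * (k - 1))
    return C


def bf_shortest_paths(adj: np.ndarray, weighted: bool) -> np.ndarray:
    """All-pairs shortest distances by enumerating every simple path."""
    n = adj.shape[0]
    lengths = np.zeros_like(adj, dtype=float)
    nz = adj > 0
    lengths[nz] = 1.0 / adj[nz] if weighted else 1.0
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)

    def explore(start: int, node: int, dist: float, visited: set) -> None:
        for nxt in range(n):
            if nz[node, nxt] and nxt not in visited:
                nd = dist + lengths[node, nxt]
                if nd < d[start, nxt]:
                    d[start, nxt] = nd
                explore(start, nxt, nd, visited | {nxt})

    for s in range(n):
        explore(s, s, 0.0, {s})
    return d


def bf_global_efficiency(adj: np.ndarray, weighted: bool) -> tuple[np.ndarray, float]:
    d = bf_shortest_paths(adj, weighted)
    n = adj.shape[0]
    if n < 2:
        return np.zeros(n), 0.0
    E = np.zeros(n)
    for i in range(n):
        E[i] = sum(1.0 / d[i, j] for j in range(n) if j != i and np.isfinite(d[i, j]))
        E[i] /= n - 1
    return E, float(E.mean())


def bf_local_efficiency(adj: np.ndarray, weighted: bool) -> np.ndarray:
    n = adj.shape[0]
    E = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j] > 0]
        if len(nbrs) < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        _, E[i] = bf_global_efficiency(sub, weighted)
    return E


def bf_path_lengths(adj: np.ndarray, weighted: bool) -> tuple[float, float]:
    """(arithmetic Lp, harmonic Lp) from the enumerated distance matrix."""
    d = bf_shortest_paths(adj, weighted)
    n = adj.shape[0]
    if n < 2:
        return 0.0, 0.0
    off = [(i, j) for i in range(n) for j in range(n) if i != j]
    arith = float(np.mean([np.mean([d[i, j] for j in range(n) if j != i]) for i in range(n)]))
    recips = [1.0 / d[i, j] if np.isfinite(d[i, j]) else 0.0 for i, j in off]
    mean_recip = float(np.mean(recips))
    harm = 1.0 / mean_recip if mean_recip > 0 else float("inf")
    return arith, harm


def bf_partial_correlation_residual(series: np.ndarray) -> np.ndarray:
    """Correlate the residuals of each pair after regressing out all others."""
    n, _t = series.shape
    out = np.zeros((n, n))
    X = series - series.mean(axis=1, keepdims=True)
    for i in range(n):
        for j in range(i + 1, n):
            others = [m for m in range(n) if m not in (i, j)]
            if others:
                Z = np.vstack([X[others], np.ones(X.shape[1])]).T
                ri = X[i] - Z @ np.linalg.lstsq(Z, X[i], rcond=None)[0]
                rj = X[j] - Z @ np.linalg.lstsq(Z, X[j], rcond=None)[0]
            else:
                ri, rj = X[i], X[j]
            out[i, j] = out[j, i] = np.corrcoef(ri, rj)[0, 1]
    return out


def bf_ranksum_exact_p(a, b) -> float:
    """Two-sided exact Mann-Whitney p by enumerating all splits (no ties)."""
    a = list(a)
    b = list(b)
    pooled = a + b
    assert len(set(pooled)) == len(pooled), "oracle assumes tie-free data"
    n1 = len(a)
    ranks = {v: r + 1 for r, v in enumerate(sorted(pooled))}
    u_obs = sum(ranks[v] for v in a) - n1 * (n1 + 1) / 2
    us = []
    for combo in combinations(range(len(pooled)), n1):
        r = sum(sorted(ranks[pooled[i]] for i in combo))
        us.append(r - n1 * (n1 + 1) / 2)
    us = np.array(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))
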