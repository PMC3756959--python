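"""Graph measures for binary and weighted brain networks.

All measures are defined for undirected networks without self-loops.  For a
binary network the connection status a_ij is 0/1; for a weighted network the
weight w_ij lies in [0, 1] (normalized at construction).  Conventions:

* degree — binary: neighbor count; weighted: summed weight (strength);
* clustering — binary: realized fraction of neighbor pairs connected;
  weighted: geometric-mean triangle intensity (cube-root weight products,
  weights renormalized by the network maximum), divided by the same
  ``k (k - 1)`` pair count, which keeps C_i <= 1; nodes with fewer than two
  neighbors get C_i = 0;
* distance — binary: minimum hop count; weighted: minimum total length with
  edge length l_ij = 1 / w_ij (strong connections are short);
* characteristic path length — arithmetic mean distance (infinities
  propagate) or the harmonic variant, the reciprocal of the mean reciprocal
  distance, which stays finite on disconnected networks;
* efficiency — mean inverse distance (1/inf = 0), globally or within each
  node's neighbor-induced subgraph;
* hierarchy — exponent beta of the power-law decline of clustering with
  degree, C(k) ~ A k^(-beta), fitted by least squares in log-log space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .construction import Network

__all__ = [
    "degree",
    "clustering",
    "shortest_paths",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
    "hierarchy_beta",
    "clustering_degree_polyfit",
    "network_summary",
    "HierarchyFit",
    "NetworkSummary",
    "EstimationError",
]


class EstimationError(RuntimeError):
    """Raised when a fit is requested on degenerate data."""


def degree(net: Network) -> tuple[np.ndarray, float]:
    """Per-node degree (binary count or weighted strength) and network mean."""
    k = net.adjacency.sum(axis=1)
    return k, float(k.mean())


def _neighbor_counts(net: Network) -> np.ndarray:
    return (net.adjacency > 0).sum(axis=1)


def clustering(net: Network) -> tuple[np.ndarray, float]:
    """Per-node clustering coefficient and its network mean Cp.

    Binary: ``C_i = 2 t_i / (k_i (k_i - 1))`` with t_i the number of links
    among the neighbors of i.  Weighted: the same formula with t_i replaced
    by the sum of cube-root products ``(w_ij w_ih w_jh)^(1/3) / ... `` over
    neighbor pairs, weights first divided by the network maximum so C_i <= 1.
    Nodes with fewer than two neighbors have C_i = 0.
    """
    A = net.adjacency
    k = _neighbor_counts(net)
    if net.mode == "binary":
        W = A
    else:
        top = A.max()
        W = A / top if top > 0 else A
    cube = np.cbrt(W)
    # diagonal of cube^3 counts each closed triangle through i twice
    tri = np.einsum("ij,jk,ki->i", cube, cube, cube) / 2.0
    denom = k * (k - 1)
    C = np.zeros(net.n_nodes)
    mask = denom > 0
    C[mask] = 2.0 * tri[mask] / denom[mask]
    return C, float(C.mean()) if net.n_nodes else 0.0


def shortest_paths(net: Network) -> np.ndarray:
    """All-pairs shortest-distance matrix.

    Binary networks use hop counts; weighted networks use edge lengths
    ``l_ij = 1 / w_ij`` (Dijkstra).  Unreachable pairs are ``inf``; the
    diagonal is 0.
    """
    A = net.adjacency
    if net.n_nodes == 0:
        return np.zeros((0, 0))
    if net.mode == "binary":
        d = _csgraph_shortest_path(A, method="D", unweighted=True, directed=False)
    else:
        lengths = np.zeros_like(A)
        nz = A > 0
        lengths[nz] = 1.0 / A[nz]
        d = _csgraph_shortest_path(lengths, method="D", directed=False)
    return d


def characteristic_path_length(
    net: Network, kind: str = "harmonic"
) -> tuple[np.ndarray, float]:
    """Per-node mean distance L_i and the network value Lp.

    ``kind="arithmetic"``: L_i is the plain mean of d_ij over j != i and Lp
    the mean of L_i; any unreachable pair makes the affected values ``inf``.
    ``kind="harmonic"``: Lp is the reciprocal of the mean of 1/d_ij over
    ordered pairs (1/inf = 0), finite for any network with at least one edge;
    a fully disconnected network has mean reciprocal 0 and Lp = ``inf``.
    """
    if kind not in ("harmonic", "arithmetic"):
        raise ValueError(f"unknown path-length kind {kind!r}")
    d = shortest_paths(net)
    n = net.n_nodes
    if n < 2:
        return np.zeros(n), 0.0
    off = ~np.eye(n, dtype=bool)
    if kind == "arithmetic":
        L_i = d.sum(axis=1, where=off) / (n - 1)  # inf propagates
        return L_i, float(L_i.mean())
    with np.errstate(divide="ignore"):
        inv = np.where(off & np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    row_mean = inv.sum(axis=1) / (n - 1)
    with np.errstate(divide="ignore"):
        L_i = np.where(row_mean > 0, 1.0 / np.where(row_mean > 0, row_mean, 1.0), np.inf)
    grand = inv[off].mean()
    Lp = float(1.0 / grand) if grand > 0 else float("inf")
    return L_i, Lp


def global_efficiency(net: Network) -> tuple[np.ndarray, float]:
    """Nodal and network global efficiency: mean inverse shortest distance."""
    d = shortest_paths(net)
    n = net.n_nodes
    if n < 2:
        return np.zeros(n), 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(off & np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    E_i = inv.sum(axis=1) / (n - 1)
    return E_i, float(E_i.mean())


def local_efficiency(net: Network) -> tuple[np.ndarray, float]:
    """Nodal local efficiency: global efficiency of the neighbor subgraph.

    Distances are computed within the subgraph induced on the neighbors of
    each node (the node itself excluded); nodes with fewer than two
    neighbors score 0.
    """
    A = net.adjacency
    n = net.n_nodes
    E = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(A[i] > 0)
        if nbrs.size < 2:
            continue
        sub = Network(A[np.ix_(nbrs, nbrs)], net.mode)
        _, E[i] = global_efficiency(sub)
    return E, float(E.mean()) if n else 0.0


@dataclass(frozen=True)
class HierarchyFit:
    """Power-law fit C(k) = A * k^(-beta) in log-log space."""

    beta: float
    intercept: float  # log A
    r_squared: float
    n_nodes: int  # eligible nodes entering the fit


def _eligible_hierarchy_nodes(net: Network) -> tuple[np.ndarray, np.ndarray]:
    k, _ = degree(net)
    C, _ = clustering(net)
    mask = (_neighbor_counts(net) >= 2) & (C > 0) & (k > 0)
    return k[mask], C[mask]


def hierarchy_beta(net: Network) -> HierarchyFit:
    """Fit the hierarchy exponent beta from the degree-clustering relation.

    Least squares of ``log C_i = log A - beta log k_i`` over nodes with at
    least two neighbors and positive clustering.  Raises
    :class:`EstimationError` when fewer than three eligible nodes remain or
    all eligible degrees coincide (slope undefined).
    """
    k, C = _eligible_hierarchy_nodes(net)
    if k.size < 3:
        raise EstimationError(f"hierarchy fit needs >= 3 eligible nodes, have {k.size}")
    x = np.log(k)
    y = np.log(C)
    if np.ptp(x) == 0:
        raise EstimationError("all eligible nodes share one degree; slope undefined")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return HierarchyFit(beta=float(-slope), intercept=float(intercept), r_squared=r2, n_nodes=int(k.size))


def clustering_degree_polyfit(net: Network, order: int = 5) -> np.ndarray:
    """Diagnostic polynomial fit of C against k (highest power first).

    A descriptive curve of the clustering-degree relation; the hierarchy
    exponent itself always comes from the power-law fit
    (:func:`hierarchy_beta`).
    """
    k, C = _eligible_hierarchy_nodes(net)
    if k.size <= order:
        raise EstimationError(f"polynomial order {order} needs > {order} eligible nodes")
    return np.polyfit(k, C, order)


@dataclass(frozen=True)
class NetworkSummary:
    """Whole-network measures bundle."""

    K_mean: float
    Cp: float
    Lp: float
    Eglob: float
    Eloc: float
    beta: float | None
    lp_kind: str

    def as_dict(self) -> dict:
        return {
            "K_mean": self.K_mean,
            "Cp": self.Cp,
            "Lp": self.Lp,
            "Eglob": self.Eglob,
            "Eloc": self.Eloc,
            "beta": self.beta,
            "lp_kind": self.lp_kind,
        }


def network_summary(net: Network, lp_kind: str = "harmonic") -> NetworkSummary:
    """Compute the standard measure set for one network.

    ``beta`` is ``None`` when the hierarchy fit is degenerate (too few
    clustered nodes or a single degree value), e.g. for empty or complete
    networks.
    """
    _, K_mean = degree(net)
    _, Cp = clustering(net)
    _, Lp = characteristic_path_length(net, kind=lp_kind)
    _, Eglob = global_efficiency(net)
    _, Eloc = local_efficiency(net)
    try:
        beta: float | None = hierarchy_beta(net).beta
    except EstimationError:
        beta = None
    return NetworkSummary(
        K_mean=K_mean, Cp=Cp, Lp=Lp, Eglob=Eglob, Eloc=Eloc, beta=beta, lp_kind=lp_kind
    )
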